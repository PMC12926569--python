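# source: synthetic stand-in; PCHIP through anchor values with the canonical oxyhemoglobin NIR-I shape (Prahl-compilation-like)
# columns: wavelength_nm	molar_absorptivity_cm-1_M-1
650.0	368
652.0	356.312
654.0	345.096
656.0	334.923
658.0	326.367
660.0	320
662.0	315.23
664.0	311.031
666.0	307.318
668.0	304.009
670.0	301.022
672.0	298.273
674.0	295.679
676.0	293.158
678.0	290.626
680.0	288
682.0	285.024
684.0	281.832
686.0	278.928
688.0	276.816
690.0	276
692.0	276.869
694.0	279.166
696.0	282.43
698.0	286.195
700.0	290
702.0	293.988
704.0	298.574
706.0	303.702
708.0	309.315
710.0	315.357
712.0	321.769
714.0	328.497
716.0	335.482
718.0	342.669
720.0	350
722.0	357.644
724.0	365.792
726.0	374.416
728.0	383.492
730.0	392.993
732.0	402.896
734.0	413.173
736.0	423.8
738.0	434.751
740.0	446
742.0	457.962
744.0	470.93
746.0	484.698
748.0	499.056
750.0	513.798
752.0	528.716
754.0	543.603
756.0	558.251
758.0	572.452
760.0	586
762.0	599.096
764.0	612.072
766.0	624.916
768.0	637.614
770.0	650.152
772.0	662.519
774.0	674.7
776.0	686.683
778.0	698.454
780.0	710
782.0	721.3
784.0	732.361
786.0	743.214
788.0	753.891
790.0	764.423
792.0	774.841
794.0	785.176
796.0	795.461
798.0	805.725
800.0	816
802.0	826.21
804.0	836.28
806.0	846.245
808.0	856.14
810.0	866
812.0	875.86
814.0	885.755
816.0	895.72
818.0	905.79
820.0	916
822.0	926.545
824.0	937.499
826.0	948.712
828.0	960.037
830.0	971.324
832.0	982.426
834.0	993.193
836.0	1003.48
838.0	1013.13
840.0	1022
842.0	1030.2
844.0	1037.97
846.0	1045.37
848.0	1052.47
850.0	1059.32
852.0	1065.99
854.0	1072.53
856.0	1079
858.0	1085.47
860.0	1092
862.0	1098.6
864.0	1105.22
866.0	1111.82
868.0	1118.35
870.0	1124.79
872.0	1131.08
874.0	1137.18
876.0	1143.07
878.0	1148.69
880.0	1154
882.0	1159.14
884.0	1164.23
886.0	1169.22
888.0	1174.08
890.0	1178.77
892.0	1183.23
894.0	1187.43
896.0	1191.32
898.0	1194.86
900.0	1198
902.0	1200.99
904.0	1204.04
906.0	1207.06
908.0	1209.97
910.0	1212.67
912.0	1215.07
914.0	1217.1
916.0	1218.65
918.0	1219.65
920.0	1220
922.0	1219.93
924.0	1219.71
926.0	1219.37
928.0	1218.9
930.0	1218.32
932.0	1217.63
934.0	1216.85
936.0	1215.98
938.0	1215.02
940.0	1214
942.0	1212.33
944.0	1209.57
946.0	1205.89
948.0	1201.48
950.0	1196.53
952.0	1191.21
954.0	1185.72
956.0	1180.23
958.0	1174.93
960.0	1170
962.0	1165.31
964.0	1160.58
966.0	1155.81
968.0	1150.97
970.0	1146.07
972.0	1141.08
974.0	1135.99
976.0	1130.79
978.0	1125.46
980.0	1120
982.0	1114.39
984.0	1108.64
986.0	1102.75
988.0	1096.73
990.0	1090.58
992.0	1084.3
994.0	1077.9
996.0	1071.38
998.0	1064.75
1000.0	1058
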