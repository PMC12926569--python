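# source: synthetic stand-in; PCHIP through anchor values with the canonical deoxyhemoglobin NIR-I shape (Prahl-compilation-like)
# columns: wavelength_nm	molar_absorptivity_cm-1_M-1
650.0	3742
652.0	3632.84
654.0	3525.91
656.0	3422.06
658.0	3322.14
660.0	3227
662.0	3135.45
664.0	3045.8
666.0	2958.14
668.0	2872.55
670.0	2789.1
672.0	2707.89
674.0	2628.99
676.0	2552.49
678.0	2478.46
680.0	2407
682.0	2338.4
684.0	2272.61
686.0	2209.19
688.0	2147.69
690.0	2087.66
692.0	2028.66
694.0	1970.24
696.0	1911.96
698.0	1853.36
700.0	1794
702.0	1733.74
704.0	1673.34
706.0	1613.65
708.0	1555.58
710.0	1500
712.0	1445.36
714.0	1390.94
716.0	1338.83
718.0	1291.15
720.0	1250
722.0	1210.81
724.0	1171.13
726.0	1136.25
728.0	1111.44
730.0	1102
732.0	1107.95
734.0	1123.77
736.0	1146.41
738.0	1172.83
740.0	1200
742.0	1230.85
744.0	1268.92
746.0	1312.06
748.0	1358.14
750.0	1405
752.0	1462.76
754.0	1533.19
756.0	1601.65
758.0	1653.47
760.0	1674
762.0	1658.91
764.0	1619.77
766.0	1565.78
768.0	1506.13
770.0	1450
772.0	1393.69
774.0	1330.64
776.0	1265.74
778.0	1203.89
780.0	1150
782.0	1100.71
784.0	1050.28
786.0	1000
788.0	951.182
790.0	905.129
792.0	863.145
794.0	826.536
796.0	796.605
798.0	774.659
800.0	762
802.0	754.967
804.0	748.933
806.0	743.761
808.0	739.31
810.0	735.443
812.0	732.021
814.0	728.904
816.0	725.954
818.0	723.033
820.0	720
822.0	716.899
824.0	713.877
826.0	710.955
828.0	708.153
830.0	705.492
832.0	702.991
834.0	700.671
836.0	698.553
838.0	696.655
840.0	695
842.0	693.454
844.0	691.9
846.0	690.378
848.0	688.928
850.0	687.59
852.0	686.405
854.0	685.413
856.0	684.655
858.0	684.17
860.0	684
862.0	684.416
864.0	685.595
866.0	687.432
868.0	689.824
870.0	692.667
872.0	695.856
874.0	699.288
876.0	702.859
878.0	706.464
880.0	710
882.0	714.264
884.0	719.845
886.0	726.328
888.0	733.296
890.0	740.333
892.0	747.024
894.0	752.952
896.0	757.701
898.0	760.856
900.0	762
902.0	761.654
904.0	760.671
906.0	759.136
908.0	757.133
910.0	754.746
912.0	752.06
914.0	749.158
916.0	746.124
918.0	743.044
920.0	740
922.0	736.661
924.0	732.713
926.0	728.272
928.0	723.452
930.0	718.368
932.0	713.134
934.0	707.866
936.0	702.678
938.0	697.684
940.0	693
942.0	688.404
944.0	683.653
946.0	678.83
948.0	674.018
950.0	669.299
952.0	664.756
954.0	660.472
956.0	656.529
958.0	653.011
960.0	650
962.0	647.349
964.0	644.852
966.0	642.507
968.0	640.309
970.0	638.254
972.0	636.339
974.0	634.56
976.0	632.913
978.0	631.394
980.0	630
982.0	628.685
984.0	627.413
986.0	626.195
988.0	625.04
990.0	623.958
992.0	622.96
994.0	622.055
996.0	621.253
998.0	620.565
1000.0	620
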