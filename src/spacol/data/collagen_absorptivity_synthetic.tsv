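# source: synthetic stand-in; analytic NIR-I collagen shape (global max 690 nm, local min ~850 nm, local max ~910 nm, local min ~940 nm)
# columns: wavelength_nm	molar_absorptivity_cm-1_M-1
650.0	3.04756
652.0	3.45758
654.0	3.91146
656.0	4.40854
658.0	4.94688
660.0	5.52317
662.0	6.13261
664.0	6.76889
666.0	7.42423
668.0	8.08946
670.0	8.75418
672.0	9.40703
674.0	10.0359
676.0	10.6286
678.0	11.1726
680.0	11.6561
682.0	12.0684
684.0	12.3997
686.0	12.6423
688.0	12.7903
690.0	12.84
692.0	12.7903
694.0	12.6423
696.0	12.3997
698.0	12.0684
700.0	11.6561
702.0	11.1726
704.0	10.6286
706.0	10.0359
708.0	9.40703
710.0	8.75418
712.0	8.08946
714.0	7.42423
716.0	6.76889
718.0	6.13261
720.0	5.52317
722.0	4.94688
724.0	4.40854
726.0	3.91146
728.0	3.45758
730.0	3.04756
732.0	2.68098
734.0	2.35647
736.0	2.07193
738.0	1.82472
740.0	1.61179
742.0	1.42989
744.0	1.27567
746.0	1.14581
748.0	1.03714
750.0	0.946638
752.0	0.871562
754.0	0.809418
756.0	0.758
758.0	0.715383
760.0	0.679915
762.0	0.650197
764.0	0.625062
766.0	0.603547
768.0	0.584871
770.0	0.568409
772.0	0.553664
774.0	0.540248
776.0	0.527863
778.0	0.516281
780.0	0.50533
782.0	0.494885
784.0	0.484853
786.0	0.475168
788.0	0.465784
790.0	0.456669
792.0	0.447803
794.0	0.439171
796.0	0.430765
798.0	0.422581
800.0	0.414616
802.0	0.406871
804.0	0.399343
806.0	0.392035
808.0	0.384947
810.0	0.378078
812.0	0.371429
814.0	0.365001
816.0	0.358791
818.0	0.3528
820.0	0.347026
822.0	0.341467
824.0	0.336123
826.0	0.33099
828.0	0.326067
830.0	0.321355
832.0	0.316853
834.0	0.312565
836.0	0.3085
838.0	0.304673
840.0	0.301114
842.0	0.297868
844.0	0.295014
846.0	0.292672
848.0	0.291025
850.0	0.290345
852.0	0.291031
854.0	0.293646
856.0	0.298975
858.0	0.308085
860.0	0.32239
862.0	0.343727
864.0	0.374414
866.0	0.417301
868.0	0.475796
870.0	0.553839
872.0	0.65583
874.0	0.78648
876.0	0.950576
878.0	1.15267
880.0	1.39668
882.0	1.68544
884.0	2.02016
886.0	2.40002
888.0	2.82164
890.0	3.27888
892.0	3.76263
894.0	4.2609
896.0	4.75924
898.0	5.24123
900.0	5.68942
902.0	6.0863
904.0	6.41543
906.0	6.66258
908.0	6.81677
910.0	6.87107
912.0	6.76632
914.0	6.45629
916.0	5.97093
918.0	5.35489
920.0	4.66085
922.0	3.94221
924.0	3.24663
926.0	2.61135
928.0	2.06092
930.0	1.60711
932.0	1.25078
934.0	0.984708
936.0	0.796765
938.0	0.672813
940.0	0.598931
942.0	0.562854
944.0	0.554678
946.0	0.567014
948.0	0.594769
950.0	0.63476
952.0	0.685283
954.0	0.745726
956.0	0.81626
958.0	0.897626
960.0	0.990989
962.0	1.09786
964.0	1.22008
966.0	1.35977
968.0	1.5194
970.0	1.70182
972.0	1.91027
974.0	2.14846
976.0	2.42062
978.0	2.73161
980.0	3.08696
982.0	3.493
984.0	3.95695
986.0	4.48708
988.0	5.09282
990.0	5.78497
992.0	6.57583
994.0	7.4795
996.0	8.51207
998.0	9.69191
1000.0	11.04
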