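# name = horvath_synthetic
# transform = loglinear
# anchor = 20
# unit = years
# score_only = false
# note = synthetic stand-in coefficients; replace with the published set for real analyses
probe_id	weight
(Intercept)	0.7
cg61269850	-1.12105
cg25082445	-0.292425
cg97298566	0.760146
cg94675294	-0.0224789
cg06441881	0.204042
cg18932038	-0.135159
cg19948593	-0.0416145
cg17929141	0.633324
cg58191327	0.397996
cg34988924	-0.0431258
cg48271795	0.44581
cg23054124	0.537233
cg95153901	-0.109583
cg67044574	0.134992
cg66409441	0.127062
cg11507938	-0.334148
cg15984529	0.57544
cg89630937	-0.0835258
cg31587375	-0.309735
cg85813048	-0.837898
cg78627295	-0.632701
cg00282703	0.762712
cg47286847	-0.570032
cg54146616	0.214777
cg46789788	-0.183573
cg10685127	0.255664
cg71948211	0.301149
cg25795495	-0.388142
cg35106348	-0.145932
cg41689604	0.0496781
cg29817348	0.0572739
cg45361612	-0.0142549
cg83794345	-0.156634
cg46814659	0.314705
cg74045639	0.658551
cg92751670	0.270252
cg21842808	-0.37007
cg25877108	0.197974
cg55813719	0.0305521
cg18789021	0.230814
cg68953470	0.922422
cg67051047	-0.106977
cg67867023	-0.00575098
cg94661870	-0.443314
cg42404206	-0.144474
cg92281087	-0.284575
cg97532212	0.799916
cg88024999	0.151987
cg30324633	-0.285959
cg06435569	0.964735
cg86055989	-0.66407
cg93669612	0.430631
cg33194228	0.508122
cg64924036	0.286973
cg16877586	-0.130576
cg87155584	-0.0646975
cg84815317	-0.171727
cg40809846	0.393037
cg78489469	-1.16446
cg21938993	-0.255621
cg96931236	0.0759721
cg79297007	-0.290583
cg81597148	-0.908796
cg66163447	-0.121414
cg04843055	-0.377583
cg77884009	0.400134
cg71110116	0.698702
cg20134469	0.0346901
cg85737965	-0.967063
cg13435173	-0.0980957
cg39886759	-0.462064
cg76362508	0.341008
cg77464165	0.845729
cg02022872	0.158713
cg25283188	1.01762
cg94560068	0.757278
cg56383992	0.348265
cg13508786	-0.430124
cg34285848	0.104444
cg60011028	-0.669595
cg00275792	0.575473
cg41900704	0.119366
cg25207192	0.749433
cg32389505	0.210116
cg63161688	-0.902139
cg17024627	0.393838
cg91475171	0.537242
cg78038280	0.904607
cg65066687	-0.412902
cg91452458	-0.387829
cg08421087	0.105954
cg72887138	-0.454263
cg88680285	-0.615866
cg60028478	-0.476298
cg54506516	1.36484
cg72363181	-0.249705
cg53608860	-0.445513
cg53399218	-0.165898
cg55826534	0.0562849
cg72554036	0.698655
cg90608386	0.525039
cg81590393	0.446083
cg28264041	0.0735828
cg87618054	0.129538
cg22221389	-0.268099
cg65510053	-0.702125
cg94696820	1.06967
cg97153358	-0.178187
cg94311667	0.556227
cg79723708	-0.108983
cg47599712	0.0034228
cg11555927	-0.0284718
cg80077800	-0.640681
cg74324997	0.00847791
cg56996087	0.237631
cg94926612	0.461319
cg35453599	0.293483
cg08170328	0.556104
cg96678937	0.192841
cg89815719	0.0422193
cg50012384	-0.939025
cg95852495	-0.224392
cg44896338	0.82012
cg95333311	0.103849
cg68676011	0.441163
cg97521266	-0.0634758
cg61647682	-0.294499
cg31787047	1.0661
cg43653632	0.221137
cg61540140	0.789614
cg29110714	0.30736
cg12552430	-0.105588
cg91866392	-1.08049
cg79621672	0.0871308
cg81881055	-0.742039
cg46692525	-1.0695
cg10246358	0.661597
cg91135486	0.402344
cg40447283	0.361932
cg13168296	0.065351
cg76340216	0.022357
cg36749336	0.251954
cg87905934	0.117978
cg60245467	0.0755337
cg96222942	0.410268
cg15452518	-1.19021
cg24072088	0.485482
cg96800128	-0.278495
cg89173684	0.465205
cg99419535	0.624403
cg69487056	-0.386486
cg99418209	0.430592
cg06820318	0.422731
cg80398163	-0.328507
cg21062884	-0.244789
cg03561031	0.073426
cg18869198	-1.10113
cg19955910	-0.212775
cg07739050	0.102331
cg40844586	-0.216098
cg68740997	-0.793525
cg67934002	-0.189842
cg31014067	0.76411
cg46839561	0.668232
cg69177326	-0.0551927
cg08170851	-0.398946
cg68651662	-0.00437785
cg87120987	0.0108192
cg17560478	-0.336035
cg69557314	-0.165027
cg25374821	0.314646
cg78216344	0.470153
cg27546215	-1.21818
cg60644791	0.491385
cg27020119	0.0701342
cg45772561	0.577744
cg73209910	-0.00770068
cg17655915	0.222347
cg94236281	0.822777
cg79510303	-1.48392
cg14544344	0.797749
cg56737306	0.0969636
cg52134160	-0.910177
cg44081378	-1.33259
cg12143311	0.157663
cg44295284	-0.512771
cg10839379	0.503674
cg60580424	0.109244
cg69675519	-0.0656086
cg49424505	0.498882
cg88878936	0.0981631
cg71705396	0.372609
cg46115928	0.417511
cg92125815	0.162073
cg79459138	0.396179
cg20258306	0.395522
cg85957316	-0.683681
cg42494939	-0.135842
cg53543079	-0.0595442
cg27035284	-0.188395
cg77549596	-0.793707
cg79083262	-0.28317
cg29294636	0.170192
cg49794611	0.0969554
cg11712914	0.762692
cg18910525	-0.302789
cg32596064	-0.215815
cg00707994	-0.285978
cg38768509	-0.157602
cg07120822	-0.301472
cg67227983	-0.935212
cg75113879	0.173046
cg35259111	0.494989
cg90332169	0.560774
cg10045220	-0.543201
cg05725455	-0.0962166
cg13503712	0.925397
cg72092886	-0.0535902
cg63425752	0.174659
cg77766012	-0.0758062
cg29870404	0.503429
cg68122731	0.484531
cg98799857	1.16417
cg49900353	0.250022
cg15383592	0.224777
cg48551807	-0.60632
cg06176032	-0.204725
cg69466874	-0.350875
cg50499250	-0.164105
cg24505267	-0.655433
cg82398640	0.608503
cg75258388	-0.526832
cg56851146	0.136823
cg19231207	-0.629956
cg29833167	0.173642
cg03518623	0.829078
cg13139596	-0.409976
cg93373090	0.182551
cg47266121	-0.0333827
cg09053097	0.141949
cg78402232	0.210412
cg60355855	-0.317756
cg05595927	-0.0899167
cg73954950	-0.294511
cg01023416	-0.412326
cg58428185	-0.614102
cg12400543	0.482713
cg43473276	-0.369056
cg92134723	0.332936
cg66099257	0.277644
cg69552966	-0.499264
cg94296370	0.52423
cg40502859	-0.430287
cg25546764	0.314436
cg00658222	0.729055
cg81035065	-0.357683
cg82835466	-0.464454
cg50925869	-0.471298
cg48489489	1.14847
cg21655933	-0.187789
cg85380244	-0.632551
cg75079244	0.407037
cg50419923	-0.0895309
cg67874414	-0.0180982
cg07836445	-0.50058
cg98115991	-1.1152
cg07374799	-0.368427
cg16974000	-0.526728
cg78981421	-0.814364
cg56974781	-0.548004
cg22244531	-0.479219
cg36101641	0.397442
cg15017842	0.347855
cg40923308	0.252723
cg26150284	-0.272359
cg51058618	-0.635029
cg27673640	0.143142
cg35026322	0.224389
cg79336860	0.495753
cg23371005	-0.0192676
cg46934858	-0.0702718
cg37478159	0.148929
cg99580003	-0.469075
cg26269314	-0.407746
cg09833248	0.315548
cg77639991	-0.63512
cg29447451	-0.0449723
cg15879260	0.3863
cg88129106	0.113862
cg71457480	0.211125
cg43536222	-0.558152
cg22452108	-0.0651939
cg76953446	-0.137764
cg38809447	0.299832
cg43307411	0.208831
cg83446113	0.0150116
cg40593660	0.951946
cg53866451	0.274503
cg88600969	-0.1395
cg30470076	-0.301738
cg31372550	-0.0124767
cg54445375	-0.279027
cg54643986	0.825355
cg20056592	0.292335
cg56456315	-0.146258
cg89898234	-0.31817
cg27709201	-0.526526
cg09893087	-0.127359
cg80339642	0.666494
cg23608269	0.43174
cg57763999	-0.0155592
cg00272549	0.0827174
cg39070541	-0.919093
cg68328310	0.393695
cg83076712	-0.0963014
cg57861683	0.702051
cg29793127	-0.0745509
cg34200102	-0.226911
cg27433323	0.12326
cg41912567	-0.302092
cg90934086	0.688484
cg04097306	0.161249
cg80732312	0.202557
cg40095731	0.186778
cg00770996	-0.15595
cg84128334	0.261876
cg18729193	0.109168
cg03784870	0.9008
cg97354450	0.0541881
cg65314676	0.211844
cg35863522	-0.202217
cg69133897	-0.158357
cg46884835	-0.123076
cg21925692	0.679213
cg07271497	0.0761895
cg29549740	0.523963
cg13143842	-0.0909338
cg17960468	-0.140756
cg44589844	-0.920429
cg56591140	0.457762
cg01679653	1.07466
cg36929491	-0.0689262
cg86164333	0.763448
cg13015358	0.471837
cg81165431	-0.29491
cg28901535	0.42982
cg79582630	-0.400106
cg24438014	-0.101147
cg68844554	0.659246
cg98686952	0.129361
cg51980560	-0.536116
cg61035023	0.756486
cg89509745	-0.49935
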