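# name = wu_synthetic
# transform = wu
# anchor = 48
# unit = months
# score_only = false
# note = synthetic stand-in coefficients; replace with the published set for real analyses
probe_id	weight
(Intercept)	-1.2
cg12857020	0.301388
cg49927786	-0.883859
cg59003284	0.173515
cg60149835	-0.125211
cg71217225	0.390761
cg02868900	-0.219531
cg48550328	-0.00912043
cg14792608	0.171426
cg40149255	-0.438131
cg92821102	0.299298
cg54775298	-0.0524816
cg07042057	0.246241
cg54274388	-0.260919
cg12977394	0.543101
cg75443746	0.302601
cg94832845	-0.0890125
cg97944567	0.315979
cg62188359	0.629878
cg86833408	0.895588
cg36899312	-0.786788
cg14574010	0.441566
cg51139002	0.232534
cg44373386	-0.0469304
cg66284295	-0.503332
cg99454015	0.628594
cg27530881	-0.630869
cg85571825	0.283473
cg13796807	0.650934
cg34774663	-0.799835
cg78803959	-0.151259
cg24762563	-0.654608
cg67036058	0.122027
cg45899437	0.757188
cg51238231	1.01178
cg94127982	-0.889057
cg81673643	-0.287475
cg83917037	0.351773
cg54907526	0.789686
cg98226757	0.210605
cg98091363	-0.373076
cg13511978	0.148566
cg20450946	-0.0083096
cg30836642	-0.10187
cg55373036	-0.367236
cg82386226	0.19363
cg48362469	0.15394
cg98376499	-0.0464921
cg35327485	-0.110844
cg92832179	-0.642458
cg59159530	-0.243088
cg72077840	0.603225
cg23530123	-0.0952791
cg59201645	-0.719849
cg80220268	0.667221
cg88669201	0.265133
cg86733355	1.05404
cg96733238	0.0312561
cg12875967	-0.230692
cg77872147	-0.723822
cg46707320	0.661919
cg68569512	1.28476
cg27714489	-0.410467
cg01457257	-0.323544
cg08311699	0.298094
cg97267191	-0.415173
cg89594430	-0.135279
cg30342832	-0.174919
cg42994869	0.0959794
cg24092039	0.547409
cg14769129	0.0110338
cg85750463	0.459455
cg67336235	-0.209944
cg07665125	0.163899
cg20221602	-1.06911
cg56372268	-0.724974
cg90143107	0.397957
cg99596793	-0.295075
cg21714825	0.289957
cg61148049	0.271172
cg03307468	0.661139
cg17456030	0.40593
cg20076895	0.508496
cg44200864	-0.0558357
cg34574787	-0.349143
cg72699532	-0.365779
cg46890816	-0.244022
cg33901369	-0.564915
cg90613433	-0.273722
cg62535330	-0.0462845
cg69736108	0.125806
cg74591373	-0.169445
cg33932066	-0.961841
cg89131070	-0.0361415
cg01687721	0.112673
cg30680159	0.542238
cg15982369	0.288932
cg00401133	-0.32178
cg99643587	-0.361888
cg08982138	1.0053
cg45971597	0.378319
cg81964781	0.91572
cg69103991	1.06472
cg85661425	-0.409042
cg05466806	0.192635
cg49720385	0.229084
cg03405027	0.279806
cg19148065	0.270951
cg84589010	0.101027
cg07317874	0.0870646
cg58788194	-0.75125
cg02015235	-0.0827006
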