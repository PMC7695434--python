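# name = epitoc_synthetic
# transform = identity
# unit = years
# score_only = true
# note = synthetic stand-in coefficients; replace with the published set for real analyses
probe_id	weight
cg89595346	1
cg86479758	1
cg81974530	1
cg85530251	1
cg06951598	1
cg81102339	1
cg94196320	1
cg26144636	1
cg16955499	1
cg07719945	1
cg79895842	1
cg94646578	1
cg60383872	1
cg61379169	1
cg00263075	1
cg83642206	1
cg91040717	1
cg13244653	1
cg98480347	1
cg84955957	1
cg28629660	1
cg47904950	1
cg81366112	1
cg90082222	1
cg08240794	1
cg65752818	1
cg43828004	1
cg34469892	1
cg81770377	1
cg68766568	1
cg40873333	1
cg88164317	1
cg51774970	1
cg85306096	1
cg11703988	1
cg91002508	1
cg81400651	1
cg53241787	1
cg49786740	1
cg31546667	1
cg24827919	1
cg27968425	1
cg77668615	1
cg38720181	1
cg97922828	1
cg38053848	1
cg53834323	1
cg39538495	1
cg73715022	1
cg35814968	1
cg99276068	1
cg64237525	1
cg03012749	1
cg95013956	1
cg59897765	1
cg69010003	1
cg96729527	1
cg28173520	1
cg11733657	1
cg68759546	1
cg22310149	1
cg01435328	1
cg55022838	1
cg54915394	1
cg72232731	1
cg90579915	1
cg55275241	1
cg24443788	1
cg54770179	1
cg06650374	1
cg05153882	1
cg10791522	1
cg73922971	1
cg32070150	1
cg08496502	1
cg07396187	1
cg12940122	1
cg95846831	1
cg15682990	1
cg65967132	1
cg61451862	1
cg45578295	1
cg47505188	1
cg73265146	1
cg80827639	1
cg47789003	1
cg66240455	1
cg12472133	1
cg93973513	1
cg60457988	1
cg68460279	1
cg74693642	1
cg26100130	1
cg74414682	1
cg96792276	1
cg55156740	1
cg31334040	1
cg92849151	1
cg77722098	1
cg94571256	1
cg71082482	1
cg87486966	1
cg77498839	1
cg37164363	1
cg78908649	1
cg26777007	1
cg93875865	1
cg52981198	1
cg52176346	1
cg65431021	1
cg31382106	1
cg16059326	1
cg71913613	1
cg55946453	1
cg71013730	1
cg43894825	1
cg00166479	1
cg68247083	1
cg41882978	1
cg08217627	1
cg39989889	1
cg04908278	1
cg96338925	1
cg21312943	1
cg05451481	1
cg73614256	1
cg92854603	1
cg27278377	1
cg90831949	1
cg21324591	1
cg67924994	1
cg18722904	1
cg16369946	1
cg79130433	1
cg49818406	1
cg16152169	1
cg82458795	1
cg32064038	1
cg31404362	1
cg66642308	1
cg21820053	1
cg42523530	1
cg73017205	1
cg46092521	1
cg52649324	1
cg30315722	1
cg89423994	1
cg03723728	1
cg06744336	1
cg36076813	1
cg71961364	1
cg82662238	1
cg57294366	1
cg83016172	1
cg69768176	1
cg08106201	1
cg63121182	1
cg55298082	1
cg73119633	1
cg35379305	1
cg32955870	1
cg39895884	1
cg32247609	1
cg98789447	1
cg09433367	1
cg80923497	1
cg47757329	1
cg50697915	1
cg00178222	1
cg50748109	1
cg85788963	1
cg91698202	1
cg37514313	1
cg86692384	1
cg78190159	1
cg72956636	1
cg97470197	1
cg73734284	1
cg12787417	1
cg45564459	1
cg41731754	1
cg68533361	1
cg46245283	1
cg83730088	1
cg08276736	1
cg29569297	1
cg80336640	1
cg76316728	1
cg76570173	1
cg48200333	1
cg03184958	1
cg53431446	1
cg02165918	1
cg46482262	1
cg34631952	1
cg37487735	1
cg22117773	1
cg75225226	1
cg46576477	1
cg39186732	1
cg92808466	1
cg18129726	1
cg50451034	1
cg78773806	1
cg55527571	1
cg39969259	1
cg45549910	1
cg57913956	1
cg81249615	1
cg98233981	1
cg73907468	1
cg64762748	1
cg12070257	1
cg52439557	1
cg03619743	1
cg28379952	1
cg41185086	1
cg70904055	1
cg61848391	1
cg96041271	1
cg70830088	1
cg50291547	1
cg76989344	1
cg74481734	1
cg31817100	1
cg31330560	1
cg60399728	1
cg35761351	1
cg90263768	1
cg47880585	1
cg76377025	1
cg89326678	1
cg56430811	1
cg46634207	1
cg86608164	1
cg17641094	1
cg93963947	1
cg53314066	1
cg90671840	1
cg25967925	1
cg91186041	1
cg63590256	1
cg33867441	1
cg95372769	1
cg95152927	1
cg60339089	1
cg43689960	1
cg55068418	1
cg58267514	1
cg02081970	1
cg58462398	1
cg18832607	1
cg41382912	1
cg46432455	1
cg97795621	1
cg94678767	1
cg04300413	1
cg42877989	1
cg74366391	1
cg84659726	1
cg26434611	1
cg40726808	1
cg07406093	1
cg17955021	1
cg15135083	1
cg75090526	1
cg39474784	1
cg90870452	1
cg17022547	1
cg77539265	1
cg34828992	1
cg28479976	1
cg29515241	1
cg49654325	1
cg89364367	1
cg11847925	1
cg58036869	1
cg41964226	1
cg62102619	1
cg25784018	1
cg28756815	1
cg03161801	1
cg96964132	1
cg29120038	1
cg13992827	1
cg92838688	1
cg51410693	1
cg53071376	1
cg56518476	1
cg27385347	1
cg04903921	1
cg11396803	1
cg93988816	1
cg89781595	1
cg79583018	1
cg09149887	1
cg57930142	1
cg03830831	1
cg20547557	1
cg11211952	1
cg90653136	1
cg75262730	1
cg74475782	1
cg93408855	1
cg63035585	1
cg09568781	1
cg13197207	1
cg63781939	1
cg33585369	1
cg65201144	1
cg32578220	1
cg52633769	1
cg85108127	1
cg00385537	1
cg56429310	1
cg69231626	1
cg29125441	1
cg43012814	1
cg76819444	1
cg93166969	1
cg57525915	1
cg99712065	1
cg29824205	1
cg63657313	1
cg41124719	1
cg11599595	1
cg68637075	1
cg31739345	1
cg56664734	1
cg62975758	1
cg59276538	1
cg87121107	1
cg92852266	1
cg42120603	1
cg11252927	1
cg36093353	1
cg45429657	1
cg60663725	1
cg51681695	1
cg85511430	1
cg83714378	1
cg19511318	1
cg36313702	1
cg59534741	1
cg48767553	1
cg61602832	1
cg97729125	1
cg47515379	1
cg89371045	1
cg36005894	1
cg63455975	1
cg94826401	1
cg79492271	1
cg81640544	1
cg24113313	1
cg15542066	1
cg47427202	1
cg00081707	1
cg73348205	1
cg25811754	1
cg32850503	1
cg42283366	1
cg37554884	1
cg16213799	1
cg97401812	1
cg33781960	1
cg83336691	1
cg68057158	1
cg15332597	1
cg73931247	1
cg04741839	1
cg81838040	1
cg30179121	1
cg81419646	1
cg35244220	1
cg32277825	1
cg12865222	1
cg53280255	1
cg98102864	1
cg73792300	1
cg83142756	1
cg61228119	1
cg57904986	1
cg57986025	1
cg48155929	1
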