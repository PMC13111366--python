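variant_id	rsid	clinvar_significance	af_overall	af_african	af_east_asian	af_european	af_latin_american	af_middle_eastern	af_south_asian	af_other
22-42124425-GC-G	rs146364112	undefined	0.999853	0.999741	0.999879	0.999859	0.999854	1	1	1
22-42121985-C-G	rs6002626	undefined	0.630385	0.916362	0.673828	0.554761	0.482042	0.653944	0.549226	0.641086
22-42132027-C-T	rs139702605	undefined	0.621885	0.666726	0.718694	0.622119	0.534851	0.663462	0.631887	0.630959
22-42130482-C-A	rs28371699	undefined	0.594349	0.745734	0.696665	0.56475	0.469289	0.635204	0.564627	0.604768
22-42121632-C-G	rs5758587	undefined	0.583091	0.729463	0.674014	0.553848	0.463014	0.632316	0.549226	0.598455
22-42134820-T-G	rs28579115	undefined	0.580161	0.689455	0.698453	0.564345	0.4641	0.608418	0.567399	0.591667
22-42122378-A-G	rs5758589	undefined	0.576616	0.705589	0.681395	0.553211	0.459154	0.620865	0.549011	0.591818
22-42127407-T-G	rs1985842	undefined	0.572727	0.653251	0.71195	0.566252	0.461802	0.622449	0.564119	0.587718
22-42135201-T-C	rs28670611	undefined	0.569587	0.644346	0.697373	0.565342	0.459806	0.622449	0.566782	0.58359
22-42126069-A-C	rs35028622	undefined	0.569164	0.644322	0.698043	0.564505	0.460297	0.622449	0.5618	0.583183
22-42135058-A-AAAC	rs141606817	undefined	0.568553	0.643824	0.697187	0.56378	0.459465	0.622762	0.561638	0.583629
22-42134089-AT-A	rs34439031	undefined	0.56763	0.640769	0.698117	0.563486	0.459086	0.621173	0.567026	0.581977
22-42132851-T-C	rs28439297	undefined	0.566975	0.637242	0.697726	0.563856	0.458878	0.621173	0.56592	0.581553
22-42132844-C-A	rs28680494	undefined	0.566853	0.636964	0.697466	0.563726	0.458885	0.62532	0.565891	0.581665
22-42133400-T-G	rs28542726	undefined	0.56676	0.63755	0.699366	0.563553	0.458094	0.623724	0.567212	0.5809
22-42125924-A-G	rs34385013	undefined	0.565621	0.642797	0.697837	0.560937	0.4533	0.620205	0.561154	0.580129
22-42129130-C-G	rs1058164	undefined	0.565598	0.637682	0.695863	0.561423	0.458332	0.621173	0.567614	0.580204
22-42130047-G-C	rs28371701	undefined	0.466265	0.381693	0.15476	0.535137	0.394679	0.561856	0.489822	0.474709
22-42123461-A-AT	rs367861743	undefined	0.399539	0.547068	0.172492	0.359728	0.351072	0.533505	0.430489	0.409407
22-42131531-G-A	rs28624811	undefined	0.376051	0.516805	0.150475	0.343226	0.317963	0.479592	0.405295	0.38041
22-42123226-C-T	rs6002629	undefined	0.36987	0.508605	0.146884	0.336977	0.314972	0.478372	0.391445	0.37653
22-42123219-C-T	rs6002628	undefined	0.369781	0.508055	0.146884	0.336978	0.314984	0.478372	0.391613	0.37643
22-42123300-A-G	rs6002632	undefined	0.369532	0.504572	0.147295	0.337366	0.315311	0.478372	0.39152	0.376581
22-42123211-T-C	rs6002627	undefined	0.369491	0.506147	0.146938	0.337012	0.314986	0.478372	0.391445	0.376388
22-42123236-T-C	rs79422943	undefined	0.369329	0.50501	0.147322	0.337013	0.314976	0.478372	0.391398	0.376337
22-42123244-A-G	rs75305438	undefined	0.369288	0.504626	0.147388	0.337027	0.315009	0.478372	0.391445	0.376454
22-42123254-A-G	rs6002631	undefined	0.369277	0.504608	0.146949	0.337051	0.31506	0.478372	0.391445	0.376388
22-42123243-C-T	rs77989876	undefined	0.369237	0.504589	0.147443	0.336967	0.314976	0.478372	0.391398	0.376312
22-42123237-G-A	rs574263560	undefined	0.369236	0.504785	0.14735	0.336921	0.314951	0.477099	0.391398	0.376296
22-42123239-C-T	rs71328648	undefined	0.36922	0.504533	0.147267	0.336976	0.31494	0.478372	0.391398	0.376312
22-42123252-G-T	rs6002630	undefined	0.36921	0.504505	0.146977	0.336989	0.314989	0.478372	0.391445	0.376337
22-42122422-G-A	rs764481	undefined	0.369184	0.504495	0.146949	0.337033	0.314704	0.478372	0.391445	0.376354
22-42123312-A-G	rs201785814	undefined	0.368997	0.501856	0.147322	0.337513	0.315346	0.477099	0.392334	0.376323
22-42123308-G-A	rs71328649	undefined	0.367634	0.498173	0.147316	0.33699	0.314309	0.477099	0.391304	0.374824
22-42123311-C-T	rs190494165	undefined	0.363745	0.496643	0.146664	0.332546	0.310983	0.451654	0.388674	0.364926
22-42127207-C-T	rs28371730	undefined	0.35111	0.420867	0.14753	0.341668	0.308087	0.469388	0.398879	0.358846
22-42132025-T-TCC	rs1297637179	undefined	0.348317	0.385728	0.585879	0.35347	0.238542	0.314607	0.298922	0.362977
22-42133533-A-C	rs28369142	undefined	0.333467	0.334001	0.151642	0.345962	0.307102	0.469388	0.404823	0.345339
22-42130565-A-G	rs1080998	undefined	0.331207	0.334847	0.150345	0.343035	0.302314	0.468112	0.405738	0.343601
22-42130547-T-C	rs1081000	undefined	0.331191	0.334806	0.150252	0.342992	0.302417	0.468112	0.405563	0.34361
22-42130559-T-G	rs28695233	undefined	0.331149	0.334678	0.150252	0.34299	0.302326	0.468112	0.405522	0.343647
22-42130578-C-G	rs1080995	undefined	0.331118	0.334684	0.150261	0.342931	0.302318	0.468112	0.40621	0.343587
22-42130560-C-G	rs29001518	undefined	0.331095	0.334638	0.150252	0.342936	0.302278	0.468112	0.405347	0.34352
22-42130569-G-C	rs1080997	undefined	0.331085	0.334669	0.150289	0.342918	0.302248	0.468112	0.405388	0.343501
22-42130571-G-T	rs1080996	undefined	0.33108	0.334609	0.150289	0.342928	0.302245	0.468112	0.405563	0.34353
22-42126132-CTGT-C	rs71184866	undefined	0.305477	0.24016	0.148369	0.339772	0.292496	0.436224	0.398966	0.319128
22-42131469-C-T	rs28633410	undefined	0.283522	0.140178	0.154326	0.344035	0.286011	0.415144	0.408141	0.297877
22-42132561-C-T	rs1080983	undefined	0.278828	0.137825	0.14918	0.337833	0.282712	0.409207	0.402844	0.293148
22-42126310-C-T	rs12169962	undefined	0.277736	0.137261	0.146505	0.336817	0.281079	0.406888	0.397458	0.291951
22-42121685-A-G	rs6002625	undefined	0.275347	0.141473	0.146791	0.331465	0.27911	0.408397	0.38951	0.291229
22-42133212-A-G	rs28568508	undefined	0.238701	0.30953	0.547699	0.222753	0.156699	0.174745	0.162284	0.242516
22-42132024-A-ATCCTT	rs1292475757	undefined	0.236283	0.135695	0.220135	0.270822	0.251175	0.312857	0.271883	0.237579
22-42132969-C-T	rs28360521	undefined	0.215068	0.218345	0.547233	0.220471	0.149664	0.151786	0.162786	0.222122
22-42125980-T-C	rs4078247	undefined	0.191925	0.121136	0.549115	0.221798	0.141607	0.141944	0.161714	0.202277
22-42133314-C-T	rs28566059	undefined	0.190771	0.119651	0.548555	0.220679	0.140395	0.142857	0.162354	0.201293
22-42121918-T-A	rs5751222	undefined	0.185621	0.113609	0.526879	0.215925	0.137419	0.139949	0.156277	0.197139
22-42123238-C-T	rs5758593	undefined	0.185477	0.113354	0.525498	0.215853	0.13737	0.139949	0.156344	0.196965
22-42132024-A-ATCCT	rs1292475757	undefined	0.14451	0.239893	0.06837	0.127311	0.081836	0.19	0.154768	0.154973
22-42129796-G-C	rs28371705	undefined	0.134468	0.037701	0.004287	0.192982	0.097807	0.110969	0.085702	0.133211
22-42125620-GGGGTGGGGAA-G	rs536156813	undefined	0.102257	0.03939	0.009302	0.134939	0.076412	0.088542	0.024459	0.122242
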