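table	variant_id	rsid	marked_subgroups	definitive
table1	22-42126611-C-G	rs1135840	east_asian	0
table1	22-42127941-G-A	rs16947	african;middle_eastern	0
table1	22-42127209-T-C	rs2004511	east_asian	0
table1	22-42128694-T-C	rs2267447	east_asian	0
table1	22-42126390-G-A	rs28371738	east_asian	0
table1	22-42132217-G-A	rs28588594	east_asian	0
table1	22-42130692-G-A	rs1065852	east_asian	0
table1	22-42131791-C-T	rs1080989	east_asian	0
table1	22-42128945-C-T	rs3892097		0
table1	22-42129809-T-C	rs3892097		0
table1	22-42129819-G-T	rs28371703		0
table2	22-42124425-GC-G	rs146364112		0
table2	22-42121985-C-G	rs6002626	african	0
table2	22-42132027-C-T	rs139702605	east_asian	0
table2	22-42130482-C-A	rs28371699	african;east_asian	1
table2	22-42121632-C-G	rs5758587	african	0
table2	22-42134820-T-G	rs28579115	african;east_asian	0
table2	22-42122378-A-G	rs5758589	african;east_asian	0
table2	22-42127407-T-G	rs1985842	east_asian	1
table2	22-42135201-T-C	rs28670611	east_asian	0
table2	22-42126069-A-C	rs35028622	east_asian	0
table2	22-42135058-A-AAAC	rs141606817	east_asian	0
table2	22-42134089-AT-A	rs34439031	east_asian	0
table2	22-42132851-T-C	rs28439297	east_asian	0
table2	22-42132844-C-A	rs28680494	east_asian	0
table2	22-42133400-T-G	rs28542726	east_asian	0
table2	22-42125924-A-G	rs34385013	east_asian	0
table2	22-42129130-C-G	rs1058164	east_asian	1
table2	22-42130047-G-C	rs28371701	middle_eastern	1
table2	22-42123461-A-AT	rs367861743	african;middle_eastern	0
table2	22-42131531-G-A	rs28624811	african;middle_eastern	1
table2	22-42123226-C-T	rs6002629	african;middle_eastern	0
table2	22-42123219-C-T	rs6002628	african;middle_eastern	0
table2	22-42123300-A-G	rs6002632	african;middle_eastern	0
table2	22-42123211-T-C	rs6002627	african;middle_eastern	0
table2	22-42123236-T-C	rs79422943	african;middle_eastern	0
table2	22-42123244-A-G	rs75305438	african;middle_eastern	0
table2	22-42123254-A-G	rs6002631	african;middle_eastern	0
table2	22-42123243-C-T	rs77989876	african;middle_eastern	0
table2	22-42123237-G-A	rs574263560	african;middle_eastern	0
table2	22-42123239-C-T	rs71328648	african;middle_eastern	0
table2	22-42123252-G-T	rs6002630	african;middle_eastern	0
table2	22-42122422-G-A	rs764481	african;middle_eastern	0
table2	22-42123312-A-G	rs201785814	african;middle_eastern	0
table2	22-42123308-G-A	rs71328649	african;middle_eastern	0
table2	22-42123311-C-T	rs190494165	african	0
table2	22-42127207-C-T	rs28371730	middle_eastern	1
table2	22-42132025-T-TCC	rs1297637179	east_asian	0
table2	22-42133533-A-C	rs28369142	middle_eastern	0
table2	22-42130565-A-G	rs1080998	middle_eastern	1
table2	22-42130547-T-C	rs1081000	middle_eastern	1
table2	22-42130559-T-G	rs28695233	middle_eastern	1
table2	22-42130578-C-G	rs1080995	middle_eastern	1
table2	22-42130560-C-G	rs29001518	middle_eastern	1
table2	22-42130569-G-C	rs1080997	middle_eastern	1
table2	22-42130571-G-T	rs1080996	middle_eastern	1
table2	22-42126132-CTGT-C	rs71184866	middle_eastern	0
table2	22-42131469-C-T	rs28633410	middle_eastern;south_asian	1
table2	22-42132561-C-T	rs1080983	middle_eastern;south_asian	0
table2	22-42126310-C-T	rs12169962	middle_eastern;south_asian	1
table2	22-42121685-A-G	rs6002625	middle_eastern;south_asian	0
table2	22-42133212-A-G	rs28568508	east_asian	0
table2	22-42132024-A-ATCCTT	rs1292475757		0
table2	22-42132969-C-T	rs28360521	east_asian	0
table2	22-42125980-T-C	rs4078247	east_asian	0
table2	22-42133314-C-T	rs28566059	east_asian	0
table2	22-42121918-T-A	rs5751222	east_asian	0
table2	22-42123238-C-T	rs5758593	east_asian	0
table2	22-42132024-A-ATCCT	rs1292475757		0
table2	22-42129796-G-C	rs28371705		0
table2	22-42125620-GGGGTGGGGAA-G	rs536156813		0
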