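variant_id	rsid	clinvar_significance	af_overall	af_african	af_east_asian	af_european	af_latin_american	af_middle_eastern	af_south_asian	af_other
22-42126611-C-G	rs1135840	drug_response	0.569155	0.643879	0.696859	0.564806	0.459859	0.622449	0.561018	0.58435
22-42127941-G-A	rs16947	drug_response	0.377418	0.522755	0.147941	0.343221	0.318624	0.479592	0.400086	0.381486
22-42127209-T-C	rs2004511	drug_response	0.200763	0.13297	0.561855	0.227836	0.149212	0.149485	0.165296	0.213165
22-42128694-T-C	rs2267447	drug_response	0.192665	0.127265	0.555369	0.220232	0.141433	0.143959	0.161207	0.20376
22-42126390-G-A	rs28371738	drug_response	0.19108	0.120567	0.528027	0.221651	0.141335	0.141582	0.159561	0.200489
22-42132217-G-A	rs28588594	drug_response	0.190967	0.120269	0.554593	0.22049	0.140363	0.143223	0.163217	0.201803
22-42130692-G-A	rs1065852	drug_response	0.190659	0.120047	0.547606	0.220477	0.140214	0.142857	0.161283	0.201099
22-42131791-C-T	rs1080989	drug_response	0.190574	0.119919	0.547521	0.220328	0.140277	0.142857	0.161499	0.201226
22-42128945-C-T	rs3892097	drug_response	0.15497	0.077924	0.006056	0.204054	0.125176	0.116368	0.104095	0.149222
22-42129809-T-C	rs3892097	drug_response	0.134322	0.037776	0.002982	0.192626	0.098207	0.110256	0.085308	0.132813
22-42129819-G-T	rs28371703	drug_response	0.133858	0.037591	0.002888	0.192304	0.097035	0.109974	0.085093	0.132002
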