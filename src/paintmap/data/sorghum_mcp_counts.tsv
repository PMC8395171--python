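probe_set	Sorghum1	Sorghum2	Sorghum3	Sorghum4	Sorghum5	Sorghum6	Sorghum7	Sorghum8	Sorghum9	Sorghum10
MCP1	27169	746	892	820	657	689	4812	2772	700	791
MCP2	701	9016	564	521	2613	11784	405	446	525	524
MCP3	711	546	20574	550	495	415	463	3761	435	513
MCP4	836	531	600	9900	5120	449	4999	564	484	543
MCP5	7236	539	552	15991	382	468	411	490	530	2548
MCP6	625	416	507	404	424	322	1390	659	10918	6910
MCP7	488	17672	421	422	316	316	387	347	367	415
MCP8	466	402	11297	420	294	282	313	372	5725	419
MCP9	8544	434	412	411	277	304	296	300	329	9614
MCP10	648	471	501	479	466	9307	2888	3983	1136	481
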