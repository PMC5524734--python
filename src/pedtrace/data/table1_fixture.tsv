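locus	snp_name	ho	he	pic	nepp
A-001	ss538953861	0.404	0.484	0.367	0.724
A-002	ss538943407	0.204	0.280	0.242	0.800
A-003	ss538953915	0.412	0.455	0.352	0.733
A-004	ss538944742	0.399	0.491	0.371	0.722
A-005	ss511222774	0.507	0.495	0.374	0.718
A-006	ss524300150	0.288	0.338	0.281	0.776
A-007	ss538941338	0.007	0.007	0.007	0.993
A-008	ss538942949	0.474	0.484	0.367	0.724
A-009	ss538954305	0.396	0.407	0.324	0.749
A-010	ss538943025	0.494	0.491	0.371	0.722
A-011	ss511222888	0.228	0.255	0.223	0.814
A-012	ss538940594	0.448	0.498	0.374	0.719
A-013	ss538942166	0.447	0.498	0.374	0.719
A-014	ss538954139	0.432	0.447	0.347	0.736
A-015	ss538943850	0.437	0.500	0.375	0.719
A-017	ss538953932	0.376	0.436	0.341	0.740
A-019	ss538953749	0.525	0.465	0.357	0.730
A-020	ss538941729	0.368	0.365	0.299	0.765
A-021	ss538942910	0.510	0.492	0.371	0.721
A-022	ss538944651	0.465	0.439	0.342	0.739
A-023	ss538942912	0.514	0.492	0.371	0.721
A-024	ss538941273	0.456	0.493	0.372	0.721
A-025	ss538946011	0.374	0.403	0.322	0.751
A-026	ss538951794	0.427	0.418	0.331	0.746
A-027	ss538945503	0.433	0.459	0.353	0.732
A-028	ss538940804	0.438	0.483	0.366	0.724
A-029	ss538945192	0.428	0.429	0.337	0.742
A-030	ss538951576	0.507	0.477	0.363	0.726
A-031	ss538940956	0.486	0.474	0.362	0.727
A-033	ss538944911	0.478	0.476	0.363	0.726
A-034	ss538945049	0.428	0.465	0.357	0.730
A-036	ss538942739	0.085	0.081	0.078	0.927
A-039	ss538945302	0.302	0.299	0.254	0.793
A-040	ss538954082	0.385	0.405	0.323	0.750
A-041	ss538940617	0.395	0.407	0.324	0.749
A-042	ss538944866	0.533	0.498	0.374	0.719
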