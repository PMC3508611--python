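mirna_id	nel_brown	nel_white	fc	direction
miR-202	1.9927	95.2234	47.7861	white
miR-424*	0.1573	1.6633	10.5741	white
miR-542-5p	0.3146	2.8514	9.0636	white
miR-424	3.2512	25.1870	7.7470	white
miR-370	0.5244	3.6236	6.9100	white
miR-22-3p	207.9226	1354.8698	6.5162	white
miR-27a-3p	71.6323	429.4856	5.9957	white
miR-450	2.0976	12.0589	5.7489	white
miR-34c	11.3794	56.1955	4.9383	white
miR-122	5.9781	28.0977	4.7001	white
miR-136	0.3146	1.2475	3.9653	white
miR-493	0.8915	3.2672	3.6648	white
miR-216a	2.9366	10.0986	3.4389	white
miR-671	2.0976	6.8908	3.2851	white
miR-494	1.0488	3.0890	2.9452	white
miR-190a	4.2476	11.7024	2.7551	white
miR-18a	4.2476	11.5836	2.7271	white
miR-124a	0.7866	2.1385	2.7187	white
miR-124b	0.7866	2.1385	2.7187	white
miR-148a	1653.0499	4265.9865	2.5807	white
miR-206	2.7269	6.8908	2.5270	white
miR-204	1.8354	4.6335	2.5245	white
miR-369-3p	3.4610	8.7323	2.5231	white
miR-345-3p	1.6256	4.0394	2.4849	white
miR-193a-3p	0.5768	1.4257	2.4718	white
miR-874	0.8915	2.1385	2.3988	white
miR-19a	2.3073	5.4057	2.3429	white
miR-143	10818.3706	24308.7093	2.2461	white
miR-1296	1.4683	3.2672	2.2252	white
miR-210	3.6708	7.9006	2.1523	white
miR-301a	0.8390	1.7821	2.1241	white
miR-27a-5p	55.0090	112.8662	2.0518	white
miR-146b	25987.7501	53201.0343	2.0472	white
miR-200a	79.7080	162.1709	2.0346	white
miR-17-3p	3.9854	8.0788	2.0271	white
miR-211	47.4053	2.9108	16.2860	brown
miR-184	232.0447	22.2762	10.4167	brown
miR-486	983.9221	151.6565	6.4878	brown
miR-885	5.1915	0.9505	5.4619	brown
miR-451	1122.4147	411.0706	2.7305	brown
miR-133a	4.1427	1.6039	2.5829	brown
miR-299	1.7829	0.7128	2.5013	brown
miR-23a	708.5623	304.5606	2.3265	brown
miR-25	504.2581	226.8017	2.2233	brown
miR-23b-3p	823.9292	371.2110	2.2196	brown
miR-1224	6.6598	3.0296	2.1982	brown
miR-15b	121.5547	58.5716	2.0753	brown
miR-193b	207.1360	100.4509	2.0620	brown
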