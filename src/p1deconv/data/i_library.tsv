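allele_id	strain_id	left_bp	right_bp	kind
i-1	SMR20792	9245	9246	intergenic-insertion
i-2	SMR20794	58336	58337	intergenic-insertion
i-3	SMR20796	107604	107605	intergenic-insertion
i-4	SMR20798	149702	149703	intergenic-insertion
i-5	SMR20800	212276	212277	intergenic-insertion
i-6	SMR20802	254217	254218	intergenic-insertion
i-7	SMR20804	302976	302977	intergenic-insertion
i-8	SMR20806	346027	346028	intergenic-insertion
i-9	SMR20808	399036	399037	intergenic-insertion
i-10	SMR20810	453467	453468	intergenic-insertion
i-11	SMR20812	502539	502540	intergenic-insertion
i-12	SMR20814	552413	552414	intergenic-insertion
i-13	SMR20816	603977	603978	intergenic-insertion
i-14	SMR20818	656768	656769	intergenic-insertion
i-15	SMR20820	698614	698615	intergenic-insertion
i-16	SMR20822	752277	752278	intergenic-insertion
i-17	SMR20824	802569	802570	intergenic-insertion
i-18	SMR20826	855083	855084	intergenic-insertion
i-19	SMR20828	903124	903125	intergenic-insertion
i-20	SMR20830	949500	949501	intergenic-insertion
i-21	SMR20832	1003907	1003908	intergenic-insertion
i-22	SMR20834	1050923	1050924	intergenic-insertion
i-23	SMR20836	1100041	1100042	intergenic-insertion
i-24	SMR20838	1145132	1145133	intergenic-insertion
i-25	SMR20840	1200628	1200629	intergenic-insertion
i-26	SMR20842	1252258	1252259	intergenic-insertion
i-27	SMR20844	1298520	1298521	intergenic-insertion
i-28	SMR20846	1349386	1349387	intergenic-insertion
i-29	SMR20848	1395674	1395675	intergenic-insertion
i-30	SMR20850	1444273	1444274	intergenic-insertion
i-31	SMR20852	1504156	1504157	intergenic-insertion
i-32	SMR20854	1550828	1550829	intergenic-insertion
i-33	SMR20856	1596574	1596575	intergenic-insertion
i-34	SMR20858	1650742	1650743	intergenic-insertion
i-35	SMR20860	1702482	1702483	intergenic-insertion
i-36	SMR20862	1752905	1752906	intergenic-insertion
i-37	SMR20864	1803323	1803324	intergenic-insertion
i-38	SMR20866	1850580	1850581	intergenic-insertion
i-39	SMR20868	1903364	1903365	intergenic-insertion
i-40	SMR20870	1950249	1950250	intergenic-insertion
i-41	SMR20872	1994102	1994103	intergenic-insertion
i-42	SMR20874	2050259	2050260	intergenic-insertion
i-43	SMR20876	2099408	2099409	intergenic-insertion
i-44	SMR20878	2149686	2149687	intergenic-insertion
i-45	SMR20880	2194391	2194392	intergenic-insertion
i-46	SMR20882	2246708	2246709	intergenic-insertion
i-47	SMR20884	2306675	2306676	intergenic-insertion
i-48	SMR20886	2347613	2347614	intergenic-insertion
i-49	SMR20888	2409420	2409421	intergenic-insertion
i-50	SMR20890	2447214	2447215	intergenic-insertion
i-51	SMR20892	2496552	2496553	intergenic-insertion
i-52	SMR20894	2547617	2547618	intergenic-insertion
i-53	SMR20896	2599009	2599010	intergenic-insertion
i-54	SMR20898	2652991	2652992	intergenic-insertion
i-55	SMR20900	2697984	2697985	intergenic-insertion
i-56	SMR20902	2755544	2755545	intergenic-insertion
i-57	SMR20904	2797657	2797658	intergenic-insertion
i-58	SMR20906	2854923	2854924	intergenic-insertion
i-59	SMR20908	2902735	2902736	intergenic-insertion
i-60	SMR20910	2944080	2944081	intergenic-insertion
i-61	SMR20912	3002010	3002011	intergenic-insertion
i-62	SMR20914	3044072	3044073	intergenic-insertion
i-63	SMR20916	3098854	3098855	intergenic-insertion
i-64	SMR20918	3152266	3152267	intergenic-insertion
i-65	SMR20920	3201326	3201327	intergenic-insertion
i-66	SMR20922	3250225	3250226	intergenic-insertion
i-67	SMR20924	3302499	3302500	intergenic-insertion
i-68	SMR20926	3352483	3352484	intergenic-insertion
i-69	SMR20928	3402513	3402514	intergenic-insertion
i-70	SMR20930	3446325	3446326	intergenic-insertion
i-71	SMR20932	3497691	3497692	intergenic-insertion
i-72	SMR20934	3544315	3544316	intergenic-insertion
i-73	SMR20936	3596557	3596558	intergenic-insertion
i-74	SMR20938	3650163	3650164	intergenic-insertion
i-75	SMR20940	3699873	3699874	intergenic-insertion
i-76	SMR20942	3749048	3749049	intergenic-insertion
i-77	SMR20944	3796247	3796248	intergenic-insertion
i-78	SMR20946	3854907	3854908	intergenic-insertion
i-79	SMR20948	3895474	3895475	intergenic-insertion
i-80	SMR20950	3946459	3946474	intergenic-insertion
i-81	SMR20952	4000422	4000423	intergenic-insertion
i-82	SMR20954	4049981	4049982	intergenic-insertion
i-83	SMR20956	4099532	4099533	intergenic-insertion
i-84	SMR20958	4148404	4148405	intergenic-insertion
i-85	SMR20960	4194294	4194295	intergenic-insertion
i-86	SMR20962	4250357	4250358	intergenic-insertion
i-87	SMR20964	4302573	4302574	intergenic-insertion
i-88	SMR20966	4351150	4351151	intergenic-insertion
i-89	SMR20968	4402627	4402628	intergenic-insertion
i-90	SMR20970	4455325	4455326	intergenic-insertion
i-91	SMR20972	4499917	4499918	intergenic-insertion
i-92	SMR20974	4553444	4553445	intergenic-insertion
i-93	SMR20976	4597553	4597569	intergenic-insertion
i-94	SMR20978	4626644	4626645	intergenic-insertion
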