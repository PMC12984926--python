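protein	site	dataset_id	loc_prob	a_score
PKN1	S562	D0007	0.9102	
PKN1	S562	D0008	0.9190	
PKN1	S562	D0009	0.8329	
PKN1	S562	D0010	0.9116	
POSP0001	S100	D0001	0.8177	
POSP0001	S100	D0009	0.8854	
NEGP0001	T200	D0005	0.9990	
NEGP0001	T200	D0006	0.7659	
NEGP0001	T200	D0010	0.9279	
NULL0001	S300	D0002	0.8280	
NULL0001	S300	D0003	0.9956	
NULL0001	S300	D0006	0.9287	
NULL0001	S300	D0007	0.9002	
NULL0001	S300	D0009	0.7740	
NULL0001	S300	D0010	0.7971	
NULL0002	S301	D0001	0.7511	
NULL0002	S301	D0008	0.7701	
NULL0003	S302	D0001	0.7886	
NULL0003	S302	D0003	0.9404	
NULL0003	S302	D0004	0.9807	
NULL0003	S302	D0010	0.7656	
NULL0004	S303	D0001	0.8201	
NULL0004	S303	D0002	0.8327	
NULL0004	S303	D0007	0.7848	
NULL0004	S303	D0010	0.7987	
NULL0005	S304	D0004	0.8907	
NULL0005	S304	D0006	0.8250	
NULL0005	S304	D0007	0.7787	
NULL0005	S304	D0008	0.8891	
NULL0006	S305	D0007	0.8347	
NULL0006	S305	D0009	0.7972	
NULL0007	S306	D0002	0.7763	
NULL0008	S307	D0001	0.8698	
NULL0009	S308	D0002	0.8278	
NULL0009	S308	D0008	0.9617	
NULL0009	S308	D0010	0.9622	
NULL0010	S309	D0002	0.8802	
NULL0010	S309	D0005	0.7894	
NULL0010	S309	D0006	0.7759	
NULL0011	S310	D0003	0.8295	
NULL0011	S310	D0004	0.8366	
NULL0011	S310	D0005	0.8963	
NULL0012	S311	D0001	0.8637	
NULL0012	S311	D0004	0.9666	
NULL0012	S311	D0006	0.8892	
NULL0012	S311	D0009	0.8872	
NULL0013	S312	D0003	0.7672	
NULL0013	S312	D0006	0.9768	
NULL0013	S312	D0009	0.8790	
NULL0013	S312	D0010	0.8129	
NULL0014	S313	D0002	0.9626	
NULL0014	S313	D0004	0.8356	
NULL0014	S313	D0006	0.8507	
NULL0014	S313	D0008	0.8822	
NULL0015	S314	D0006	0.8411	
NULL0015	S314	D0007	0.9697	
NULL0016	S315	D0005	0.7517	
NULL0016	S315	D0006	0.8220	
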