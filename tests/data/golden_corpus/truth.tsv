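protein	site	role	detection_prob	agreement_prob
PKN1	S562	anchor	0.5	
POSP0001	S100	positive_partner	0.9	0.9
NEGP0001	T200	negative_partner	0.9	0.9
NULL0001	S300	null	0.25	
NULL0002	S301	null	0.25	
NULL0003	S302	null	0.25	
NULL0004	S303	null	0.25	
NULL0005	S304	null	0.25	
NULL0006	S305	null	0.25	
NULL0007	S306	null	0.25	
NULL0008	S307	null	0.25	
NULL0009	S308	null	0.25	
NULL0010	S309	null	0.25	
NULL0011	S310	null	0.25	
NULL0012	S311	null	0.25	
NULL0013	S312	null	0.25	
NULL0014	S313	null	0.25	
NULL0015	S314	null	0.25	
NULL0016	S315	null	0.25	
NULL0017	S316	null	0.25	
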