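condition_code	pmid
C00001	PMID0000001
C00002	PMID0000001
C00003	PMID0000001
C00004	PMID0000002
C00005	PMID0000002
C00006	PMID0000002
C00007	PMID0000003
C00008	PMID0000003
C00009	PMID0000003
C00010	PMID0000004
C00011	PMID0000004
C00012	PMID0000004
C00013	PMID0000005
C00014	PMID0000005
C00015	PMID0000005
C00016	PMID0000006
C00017	PMID0000006
C00018	PMID0000006
C00019	PMID0000007
C00020	PMID0000007
C00021	PMID0000007
C00022	PMID0000008
C00023	PMID0000008
C00024	PMID0000008
C00025	PMID0000009
C00026	PMID0000009
C00027	PMID0000009
C00028	PMID0000010
C00029	PMID0000010
C00030	PMID0000010
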