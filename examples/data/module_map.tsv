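ko_id	module_id
K00001	M0001
K00028	M0001
K00010	M0001
K00011	M0001
K00004	M0002
K00019	M0002
K00013	M0002
K00023	M0003
K00014	M0003
K00015	M0003
K00022	M0003
K00024	M0003
K00027	M0004
K00021	M0004
K00026	M0004
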