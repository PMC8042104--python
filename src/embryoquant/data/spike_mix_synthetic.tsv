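# Synthetic stand-in for a 92-species spike-in mix: deterministic
# log-spaced abundance ladder spanning 1e2-1e7 molecules per
# embryo-equivalent. Not vendor concentrations.
spike_id	molecules_per_embryo
ERCC-SYN-001	100
ERCC-SYN-002	113.487
ERCC-SYN-003	128.792
ERCC-SYN-004	146.162
ERCC-SYN-005	165.875
ERCC-SYN-006	188.246
ERCC-SYN-007	213.634
ERCC-SYN-008	242.446
ERCC-SYN-009	275.144
ERCC-SYN-010	312.252
ERCC-SYN-011	354.365
ERCC-SYN-012	402.157
ERCC-SYN-013	456.395
ERCC-SYN-014	517.947
ERCC-SYN-015	587.802
ERCC-SYN-016	667.077
ERCC-SYN-017	757.044
ERCC-SYN-018	859.144
ERCC-SYN-019	975.014
ERCC-SYN-020	1106.51
ERCC-SYN-021	1255.74
ERCC-SYN-022	1425.1
ERCC-SYN-023	1617.3
ERCC-SYN-024	1835.42
ERCC-SYN-025	2082.96
ERCC-SYN-026	2363.89
ERCC-SYN-027	2682.7
ERCC-SYN-028	3044.5
ERCC-SYN-029	3455.11
ERCC-SYN-030	3921.09
ERCC-SYN-031	4449.91
ERCC-SYN-032	5050.06
ERCC-SYN-033	5731.15
ERCC-SYN-034	6504.09
ERCC-SYN-035	7381.28
ERCC-SYN-036	8376.78
ERCC-SYN-037	9506.53
ERCC-SYN-038	10788.6
ERCC-SYN-039	12243.7
ERCC-SYN-040	13895
ERCC-SYN-041	15768.9
ERCC-SYN-042	17895.6
ERCC-SYN-043	20309.2
ERCC-SYN-044	23048.2
ERCC-SYN-045	26156.7
ERCC-SYN-046	29684.3
ERCC-SYN-047	33687.8
ERCC-SYN-048	38231.2
ERCC-SYN-049	43387.3
ERCC-SYN-050	49238.8
ERCC-SYN-051	55879.5
ERCC-SYN-052	63415.8
ERCC-SYN-053	71968.6
ERCC-SYN-054	81674.8
ERCC-SYN-055	92690
ERCC-SYN-056	105191
ERCC-SYN-057	119378
ERCC-SYN-058	135478
ERCC-SYN-059	153749
ERCC-SYN-060	174485
ERCC-SYN-061	198017
ERCC-SYN-062	224723
ERCC-SYN-063	255031
ERCC-SYN-064	289427
ERCC-SYN-065	328461
ERCC-SYN-066	372759
ERCC-SYN-067	423032
ERCC-SYN-068	480086
ERCC-SYN-069	544833
ERCC-SYN-070	618314
ERCC-SYN-071	701704
ERCC-SYN-072	796341
ERCC-SYN-073	903741
ERCC-SYN-074	1.02563e+06
ERCC-SYN-075	1.16395e+06
ERCC-SYN-076	1.32093e+06
ERCC-SYN-077	1.49908e+06
ERCC-SYN-078	1.70125e+06
ERCC-SYN-079	1.9307e+06
ERCC-SYN-080	2.19109e+06
ERCC-SYN-081	2.48659e+06
ERCC-SYN-082	2.82195e+06
ERCC-SYN-083	3.20254e+06
ERCC-SYN-084	3.63446e+06
ERCC-SYN-085	4.12463e+06
ERCC-SYN-086	4.6809e+06
ERCC-SYN-087	5.3122e+06
ERCC-SYN-088	6.02865e+06
ERCC-SYN-089	6.84171e+06
ERCC-SYN-090	7.76444e+06
ERCC-SYN-091	8.8116e+06
ERCC-SYN-092	1e+07
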