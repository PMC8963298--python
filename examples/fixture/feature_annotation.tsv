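feature_id	is_xenobiotic	is_derived
met_001	FALSE	FALSE
met_002	FALSE	FALSE
met_003	FALSE	FALSE
met_004	FALSE	FALSE
met_005	FALSE	FALSE
met_006	FALSE	FALSE
met_007	FALSE	FALSE
met_008	FALSE	FALSE
met_009	FALSE	FALSE
met_010	FALSE	FALSE
met_011	FALSE	FALSE
met_012	FALSE	FALSE
met_013	FALSE	FALSE
met_014	FALSE	FALSE
met_015	FALSE	FALSE
met_016	FALSE	FALSE
met_017	FALSE	FALSE
met_018	FALSE	FALSE
met_019	FALSE	FALSE
met_020	FALSE	FALSE
xeno_1	TRUE	FALSE
xeno_2	TRUE	FALSE
ratio_1	FALSE	TRUE
ratio_2	FALSE	TRUE
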