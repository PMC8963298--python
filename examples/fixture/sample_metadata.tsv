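sample_id	batch	run_day
S001	B1	day1
S002	B2	day1
S003	B1	day1
S004	B2	day1
S005	B1	day1
S006	B2	day1
S007	B1	day1
S008	B2	day1
S009	B1	day1
S010	B2	day1
S011	B1	day1
S012	B2	day1
S013	B1	day1
S014	B2	day1
S015	B1	day1
S016	B2	day1
S017	B1	day1
S018	B2	day1
S019	B1	day1
S020	B2	day1
S021	B1	day2
S022	B2	day2
S023	B1	day2
S024	B2	day2
S025	B1	day2
S026	B2	day2
S027	B1	day2
S028	B2	day2
S029	B1	day2
S030	B2	day2
S031	B1	day2
S032	B2	day2
S033	B1	day2
S034	B2	day2
S035	B1	day2
S036	B2	day2
S037	B1	day2
S038	B2	day2
S039	B1	day2
S040	B2	day2
S041	B1	day3
S042	B2	day3
S043	B1	day3
S044	B2	day3
S045	B1	day3
S046	B2	day3
S047	B1	day3
S048	B2	day3
S049	B1	day3
S050	B2	day3
S051	B1	day3
S052	B2	day3
S053	B1	day3
S054	B2	day3
S055	B1	day3
S056	B2	day3
S057	B1	day3
S058	B2	day3
S059	B1	day3
S060	B2	day3
S061	B1	day4
S062	B2	day4
S063	B1	day4
S064	B2	day4
S065	B1	day4
S066	B2	day4
S067	B1	day4
S068	B2	day4
S069	B1	day4
S070	B2	day4
S071	B1	day4
S072	B2	day4
S073	B1	day4
S074	B2	day4
S075	B1	day4
S076	B2	day4
S077	B1	day4
S078	B2	day4
S079	B1	day4
S080	B2	day4
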