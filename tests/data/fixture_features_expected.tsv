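sirna_id	efficacy_code	loop5	loop3	int_loop	mb_loop	h_loop	b_loop	one_bb	stem	n_unpaired	runs	max_run	hb_index	dg_overall	dg_duplex	dg_break_target	dg_oligo_self	gc_percent
FIXS1	1	3	0	2	0	4	0	0	10	9	3,2,4	4	17.4000	-4.9600	-34.9600	-27.0000	-3.0000	52.6316
FIXS2	0	0	3	2	0	4	0	0	10	9	4,2,3	4	18.6000	0.0900	-34.9100	-27.0000	-8.0000	52.6316
FIXS3	1	3	0	0	0	4	2	1	9	10	3,2,1,4	4	16.5000	-6.4400	-33.4400	-27.0000	0.0000	47.3684
FIXS4	0	0	3	0	0	4	0	1	11	8	1,4,3	4	21.0000	-0.7800	-37.7800	-27.0000	-10.0000	57.8947
FIXS5	1	0	0	0	2	4	0	0	13	6	1,4,1	4	24.0000	-2.2500	-41.2500	-30.0000	-9.0000	68.4211
FIXS6	0	0	2	0	2	4	0	0	11	8	1,4,1,2	4	23.4000	-0.2400	-37.2400	-24.0000	-13.0000	57.8947
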