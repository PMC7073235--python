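# Published NSR/TFP prediction scores for 12 CRC miRNA biomarkers,
# as reported on an RNA-seq platform and a microarray platform.
mirna_id	platform	nsr	p_nsr	tfp	p_tfp
miRNA-155-5p	rnaseq	22	1.75e-46	0.2338	7.41e-16
miRNA-30e-5p	rnaseq	17	1.42e-43	0.1656	0.015286
miRNA-21-5p	rnaseq	16	6.67e-43	0.1915	1.27e-7
miRNA-98-5p	rnaseq	12	9.58e-35	0.1875	8.76e-7
miRNA-200c-3p	rnaseq	9	2.31e-21	0.1792	5.81e-5
miRNA-204-5p	rnaseq	9	2.31e-21	0.2277	7.17e-15
miRNA-146a-5p	rnaseq	8	3.61e-17	0.175	4.72e-4
let-7g-5p	rnaseq	7	1.11e-14	0.1681	0.006026
miRNA-10b-5p	rnaseq	6	7.62e-11	0.25	2.43e-17
miRNA-31-5p	rnaseq	6	7.62e-11	0.1667	0.008075
miRNA-186-5p	rnaseq	5	1.30e-6	0.1667	0.008075
miRNA-222-3p	rnaseq	4	0.013019	0.2222	3.09e-14
miRNA-155-5p	microarray	2	2.16e-19	0.375	1.39e-17
miRNA-30e-5p	microarray	8	7.17e-43	0.1892	0.012712
miRNA-21-5p	microarray	6	5.74e-42	0.2	0.001904
miRNA-98-5p	microarray	1	1.78e-5	0.25	1.02e-8
miRNA-200c-3p	microarray	5	2.40e-40	0.186	0.022552
miRNA-204-5p	microarray	4	2.04e-35	0.2121	1.70e-4
miRNA-146a-5p	microarray	2	2.16e-19	0.25	1.02e-8
let-7g-5p	microarray	2	2.16e-19	0.2143	1.15e-4
miRNA-10b-5p	microarray	1	1.78e-5	0.25	1.02e-8
miRNA-31-5p	microarray	1	1.78e-5	0.2	0.001904
miRNA-186-5p	microarray	1	1.78e-5	0.2	0.001904
miRNA-222-3p	microarray	1	1.78e-5	0.2857	5.82e-12
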