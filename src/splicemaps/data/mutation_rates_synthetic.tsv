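# Synthetic strand-collapsed trinucleotide mutability table (96 rows).
# Placeholder rates with a realistic spread (CpG transitions elevated);
# swap in an empirically estimated table for real-data analyses.
context	alt	rate
AAA	C	0.303159
AAA	G	0.809631
AAA	T	1.251549
AAC	C	1.534809
AAC	G	1.068094
AAC	T	0.477076
AAG	C	0.703563
AAG	G	0.848681
AAG	T	0.79426
AAT	C	0.823574
AAT	G	0.581337
AAT	T	0.630323
CAA	C	0.392709
CAA	G	1.378698
CAA	T	0.748296
CAC	C	1.117248
CAC	G	0.990822
CAC	T	0.799029
CAG	C	0.682358
CAG	G	0.932482
CAG	T	0.719892
CAT	C	0.731703
CAT	G	0.867825
CAT	T	1.186719
GAA	C	1.072945
GAA	G	0.801841
GAA	T	1.01313
GAC	C	0.795382
GAC	G	0.41078
GAC	T	0.724627
GAG	C	0.362536
GAG	G	1.553098
GAG	T	1.367126
GAT	C	1.554451
GAT	G	0.562749
GAT	T	0.961619
TAA	C	1.151023
TAA	G	0.415831
TAA	T	0.774935
TAC	C	0.982718
TAC	G	0.73579
TAC	T	0.716155
TAG	C	0.80825
TAG	G	0.572468
TAG	T	0.496956
TAT	C	0.917753
TAT	G	0.867443
TAT	T	0.50556
ACA	A	0.609754
ACA	G	0.729595
ACA	T	0.443685
ACC	A	1.505742
ACC	G	1.090673
ACC	T	1.214053
ACG	A	0.570674
ACG	G	1.337936
ACG	T	4.134322
ACT	A	0.473704
ACT	G	1.276341
ACT	T	0.47712
CCA	A	0.720385
CCA	G	0.997592
CCA	T	1.036703
CCC	A	1.75819
CCC	G	1.315342
CCC	T	0.413206
CCG	A	0.588057
CCG	G	0.64626
CCG	T	5.404805
CCT	A	0.707299
CCT	G	0.820233
CCT	T	0.364708
GCA	A	1.366715
GCA	G	0.691627
GCA	T	0.53382
GCC	A	0.716613
GCC	G	0.895883
GCC	T	0.763554
GCG	A	0.464824
GCG	G	1.349861
GCG	T	4.330342
GCT	A	0.639842
GCT	G	0.834254
GCT	T	0.862323
TCA	A	1.007117
TCA	G	1.718994
TCA	T	0.376391
TCC	A	0.797083
TCC	G	0.64241
TCC	T	0.806264
TCG	A	1.01857
TCG	G	1.068043
TCG	T	3.402724
TCT	A	0.537773
TCT	G	1.035148
TCT	T	1.004445
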