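gene	chrom	pos	ref_base	alt_base	codon_change	defining_subtype	source
PAX5	9	37015167	G	C	P80R	PAX5 P80R	synthetic-curation-v1
IKZF1	7	50382593	A	T	N159Y	IKZF1 N159Y	synthetic-curation-v1
ZEB2	2	144389982	T	C	H1038R	ZEB2 H1038R	synthetic-curation-v1
NRAS	1	114716126	C	T	G12D		synthetic-curation-v1
NRAS	1	114716125	C	T	G12S		synthetic-curation-v1
NRAS	1	114716124	C	A	G12C		synthetic-curation-v1
NRAS	1	114716123	C	A	G12V		synthetic-curation-v1
NRAS	1	114716122	C	G	G12A		synthetic-curation-v1
NRAS	1	114716121	C	T	G13D		synthetic-curation-v1
NRAS	1	114716120	C	G	G13R		synthetic-curation-v1
NRAS	1	114716119	G	T	Q61K		synthetic-curation-v1
NRAS	1	114716118	T	C	Q61R		synthetic-curation-v1
NRAS	1	114716117	T	A	Q61L		synthetic-curation-v1
NRAS	1	114716116	G	T	Q61H		synthetic-curation-v1
KRAS	12	25245350	C	T	G12D		synthetic-curation-v1
KRAS	12	25245349	C	A	G12V		synthetic-curation-v1
KRAS	12	25245348	C	A	G12C		synthetic-curation-v1
KRAS	12	25245347	C	T	G12S		synthetic-curation-v1
KRAS	12	25245346	C	G	G12A		synthetic-curation-v1
KRAS	12	25245345	C	T	G13D		synthetic-curation-v1
KRAS	12	25245344	C	T	A146T		synthetic-curation-v1
KRAS	12	25245343	T	G	Q61H		synthetic-curation-v1
FLT3	13	28018505	C	A	D835Y		synthetic-curation-v1
FLT3	13	28018504	T	A	D835V		synthetic-curation-v1
FLT3	13	28018503	C	G	D835H		synthetic-curation-v1
FLT3	13	28018502	T	C	D839G		synthetic-curation-v1
FLT3	13	28018501	G	T	N676K		synthetic-curation-v1
FLT3	13	28018500	T	C	Y842C		synthetic-curation-v1
CRLF2	X	1212750	T	G	F232C		synthetic-curation-v1
JAK1	1	64846500	C	A	V658F		synthetic-curation-v1
JAK1	1	64846499	C	A	S703I		synthetic-curation-v1
JAK1	1	64846498	C	T	R724H		synthetic-curation-v1
JAK2	9	5073770	A	G	R683G		synthetic-curation-v1
JAK2	9	5073771	A	T	R683S		synthetic-curation-v1
JAK2	9	5073772	A	T	I682F		synthetic-curation-v1
TP53	17	7674220	C	T	R175H		synthetic-curation-v1
TP53	17	7674219	T	C	Y220C		synthetic-curation-v1
TP53	17	7674218	C	T	R248Q		synthetic-curation-v1
TP53	17	7674217	G	A	R248W		synthetic-curation-v1
TP53	17	7674216	C	T	R273H		synthetic-curation-v1
TP53	17	7674215	G	A	R273C		synthetic-curation-v1
TP53	17	7674214	G	A	R282W		synthetic-curation-v1
IDH1	2	208248388	C	T	R132H		synthetic-curation-v1
IDH1	2	208248389	G	A	R132C		synthetic-curation-v1
IDH2	15	90088702	C	T	R140Q		synthetic-curation-v1
IDH2	15	90088606	C	T	R172K		synthetic-curation-v1
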