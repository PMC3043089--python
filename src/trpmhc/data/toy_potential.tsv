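# trpmhc potential table
#table_id	toy-residue-v1
#typing	residue
#bin_edges	0	2	4	6	8
type_i	type_j	bin_index	u_bar
ALA	ALA	0	0.5
ALA	ALA	1	-0.05
ALA	ALA	2	-0.05
ALA	ARG	0	0.6
ALA	ARG	1	-0.1
ALA	ARG	2	-0.1
ALA	ASP	0	0.6
ALA	ASP	1	-0.1
ALA	ASP	2	-0.1
ALA	GLU	0	0.6
ALA	GLU	1	-0.1
ALA	GLU	2	-0.1
ALA	GLY	0	0.5
ALA	GLY	1	-0.05
ALA	GLY	2	-0.05
ALA	HIS	0	0.6
ALA	HIS	1	-0.1
ALA	HIS	2	-0.1
ALA	LYS	0	0.6
ALA	LYS	1	-0.1
ALA	LYS	2	-0.1
ARG	ARG	0	1
ARG	ARG	1	0.6
ARG	ARG	2	0.6
ARG	ARG	3	0.2
ARG	ASP	0	0.8
ARG	ASP	1	-1
ARG	ASP	2	-1
ARG	ASP	3	-0.3
ARG	GLU	0	0.8
ARG	GLU	1	-1
ARG	GLU	2	-1
ARG	GLU	3	-0.3
ARG	GLY	0	0.6
ARG	GLY	1	-0.1
ARG	GLY	2	-0.1
ARG	HIS	0	1
ARG	HIS	1	0.6
ARG	HIS	2	0.6
ARG	HIS	3	0.2
ARG	LYS	0	1
ARG	LYS	1	0.6
ARG	LYS	2	0.6
ARG	LYS	3	0.2
ASP	ASP	0	1
ASP	ASP	1	0.6
ASP	ASP	2	0.6
ASP	ASP	3	0.2
ASP	GLU	0	1
ASP	GLU	1	0.6
ASP	GLU	2	0.6
ASP	GLU	3	0.2
ASP	GLY	0	0.6
ASP	GLY	1	-0.1
ASP	GLY	2	-0.1
ASP	HIS	0	0.8
ASP	HIS	1	-1
ASP	HIS	2	-1
ASP	HIS	3	-0.3
ASP	LYS	0	0.8
ASP	LYS	1	-1
ASP	LYS	2	-1
ASP	LYS	3	-0.3
GLU	GLU	0	1
GLU	GLU	1	0.6
GLU	GLU	2	0.6
GLU	GLU	3	0.2
GLU	GLY	0	0.6
GLU	GLY	1	-0.1
GLU	GLY	2	-0.1
GLU	HIS	0	0.8
GLU	HIS	1	-1
GLU	HIS	2	-1
GLU	HIS	3	-0.3
GLU	LYS	0	0.8
GLU	LYS	1	-1
GLU	LYS	2	-1
GLU	LYS	3	-0.3
GLY	GLY	0	0.5
GLY	GLY	1	-0.05
GLY	GLY	2	-0.05
GLY	HIS	0	0.6
GLY	HIS	1	-0.1
GLY	HIS	2	-0.1
GLY	LYS	0	0.6
GLY	LYS	1	-0.1
GLY	LYS	2	-0.1
HIS	HIS	0	1
HIS	HIS	1	0.6
HIS	HIS	2	0.6
HIS	HIS	3	0.2
HIS	LYS	0	1
HIS	LYS	1	0.6
HIS	LYS	2	0.6
HIS	LYS	3	0.2
LYS	LYS	0	1
LYS	LYS	1	0.6
LYS	LYS	2	0.6
LYS	LYS	3	0.2
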