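position	enzyme	condition	intensity
23	T1	fold	weak
31	T1	fold	weak
48	T1	fold	weak
75	T1	fold	weak
23	T1	denature	strong
31	T1	denature	strong
48	T1	denature	strong
75	T1	denature	strong
31	V1	fold	strong
32	V1	fold	weak
33	V1	fold	strong
45	V1	fold	strong
46	V1	fold	strong
47	V1	fold	weak
48	V1	fold	strong
49	V1	fold	strong
56	V1	fold	strong
57	V1	fold	strong
58	V1	fold	weak
59	V1	fold	strong
60	V1	fold	strong
61	V1	fold	strong
62	V1	fold	weak
63	V1	fold	strong
64	V1	fold	strong
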