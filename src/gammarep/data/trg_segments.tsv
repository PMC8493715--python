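id	segment_type	family	family_index	functional_status	anchor_offset	rss	locus_start	locus_end	motif_block
TRGV4.1	V	TRGV4	1	pseudogene			0	136	block1
TRGV1.1	V	TRGV1	1	pseudogene			396	532	block1
TRGV3.1	V	TRGV3	1	functional	129	CACAGTGTATGCAACTTACTTCGGGCGCTCATCAAAACC	792	933	block1
TRGV2.1	V	TRGV2	1	functional	129	CACAGAGACAGAAGTGGGACACACTGCAACACGAAAACC	1193	1334	block1
TRGV2.2	V	TRGV2	2	pseudogene			1594	1730	block1
TRGV2.3	V	TRGV2	3	pseudogene			1990	2126	block1
TRGV2.4	V	TRGV2	4	functional	129	CTCAGTTACGGGTAAGGTCTGGGCACAGTAACAAACTCC	2386	2527	block1
TRGV4.2	V	TRGV4	2	functional	129	CTCGCTGGACCATCCGGCCTACCTAAATTCACAAAGACC	2787	2928	block2
TRGV1.2	V	TRGV1	2	not_detected_expressed	129	CACAATTCTCTCTGTCCTCGCTGCACTCGTGCAAAAACG	3188	3329	block2
TRGV3.2	V	TRGV3	2	functional	129	CACAGTGTCACATTATACATGTTTGAAAGGACAAAAACC	3589	3730	block2
TRGV2.5	V	TRGV2	5	pseudogene			3990	4126	block2
TRGV2.6	V	TRGV2	6	pseudogene			4386	4522	block2
TRGV2.7	V	TRGV2	7	functional	129	CGCAGAGCACGCCCCAATGGCATCAACAAAACAAAAACG	4782	4923	block2
TRGV2.8	V	TRGV2	8	functional	129	CTCAGTTACGGGTAAGGTCTGGGCACAGTAACAAACTCC	5183	5324	block2
TRGV4.3	V	TRGV4	3	pseudogene			5584	5720	block3
TRGV1.3	V	TRGV1	3	functional	129	CACAGAAGCTCAGATCTTTCCATTTCCGAAACCAAAACC	5980	6121	block3
TRGV3.3	V	TRGV3	3	functional	129	CACGGCATAACCGAACAGCCCGGACTAGCTACAAAAACC	6381	6522	block3
TRGV2.9	V	TRGV2	9	not_detected_expressed	129	CACAGTGATAGTGAAGAACGGTTGCGGATCACAAAAAAC	6782	6923	block3
TRGV2.10	V	TRGV2	10	pseudogene			7183	7319	block3
TRGV2.11	V	TRGV2	11	functional	129	CAACGTGTATCATTCGGCACGCTGCCCAGCACAAATACC	7579	7720	block3
TRGV2.12	V	TRGV2	12	functional	129	AACTGAGTATTGCGGATGCTGATCAACTTCAGGAAAACC	7980	8121	block3
TRGV4.4	V	TRGV4	4	functional	129	CTCGTTGGCGCAGAGCGGTAGAGCAGTGAAACAAAAACC	8381	8522	block4
TRGV1.4	V	TRGV1	4	pseudogene			8782	8918	block4
TRGV3.4	V	TRGV3	4	functional	129	CACAGTGAAATCGTTCGTCTCAACAACGAAACAAGAACC	9178	9319	block4
TRGV2.13	V	TRGV2	13	functional	129	CACGGTGCGGCTGTGCCAAATGAAGTGTACACAAAAACC	9579	9720	block4
TRGV2.14	V	TRGV2	14	functional	129	CTCAGTTACGGGTAAGGTCTGGGCACAGTAACAAACTCC	9980	10121	block4
TRGV2.15	V	TRGV2	15	functional	129	CACACTGTGCTAACGGTACCTGTACCAATAACAAAAACC	10381	10522	block4
TRGV2.16	V	TRGV2	16	pseudogene			10782	10918	block4
TRGV4.5	V	TRGV4	5	pseudogene			11178	11314	block5
TRGV1.5	V	TRGV1	5	functional	129	CACAGTGTTACTTTATTGGCCTGATATTTTACAAAAACC	11574	11715	block5
TRGV3.5	V	TRGV3	5	functional	129	CTCAGCCTGACTCGCCCGGATTAGCGGTAGACAAAAACC	11975	12116	block5
TRGV2.17	V	TRGV2	17	pseudogene			12376	12512	block5
TRGV2.18	V	TRGV2	18	functional	129	CGCAGAGCACGCCCCAATGGCATCAACAAAACAAAAACG	12772	12913	block5
TRGV2.19	V	TRGV2	19	functional	129	CTCAGTTACGGGTAAGGTCTGGGCACAGTAACAAACTCC	13173	13314	block5
TRGV2.20	V	TRGV2	20	functional	129	CACGGTCGAGTGCATGGTGGTGCTCCTAAAAAAAAAACC	13574	13715	block5
TRGV1.6	V	TRGV1	6	functional	129	CATTGTGTAAACAAATCAATTTAGCCGGGTACCAAAACC	13975	14116	block6
TRGV3.6	V	TRGV3	6	functional	129	GTAAGTGGATTCTCCGTAACCAAACATCCCCCTAAAACC	14376	14517	block6
TRGV2.21	V	TRGV2	21	pseudogene			14777	14913	block6
TRGV2.22	V	TRGV2	22	functional	129	CCAACTGTCTTGCCACTGCCTCGTATTAAAATAAAAACC	15173	15314	block6
TRGV3.7	V	TRGV3	7	functional	129	AACAGCGGCACTCCTGTCATAGACGATTAAACAAAAACC	15574	15715	block7
TRGJ1	J		1	functional	12	CACAGTGCGAACTATCAAGCACAATTACCGACAAAAACC	15975	16023	
TRGJ2	J		2	functional	12	CACAGTGGTTGGGAGCAGTAAGCATGGACCACAAAAACC	16173	16221	
TRGJ3	J		3	functional	12	CACAGTGAATAGGTGTGTGTAGCATAAAGAACAAAAACC	16371	16419	
TRGC	C		1	functional			16569	16689	
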