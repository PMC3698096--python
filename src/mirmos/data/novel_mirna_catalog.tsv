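name	sequence	longest_extension	contig	start	end	strand	section
aal-miR-new1	AAAGCAACCGAACAATTGTCCA	.	25767	26526	26448	-	mosquito
aal-miR-new1*	TGGCTTTTGCTTGGTAGCCTCA	.	25767	26526	26448	-	mosquito
aal-miR-new2	ATTAGAATGTGGAATCTGTTTT	.	21646	21603	21512	-	mosquito
aal-miR-new2*	AAAAGTTTTCATATTCTTGCG	G	21646	21603	21512	-	mosquito
aal-miR-new3-1	TTCCTGACTTATACGCTTACCT	.	8458	2362	2439	+	culicinae
aal-miR-new3-1*	TAAGTAGATAAATCAGAAAGA	.	8458	2362	2439	+	culicinae
aal-miR-new3-2	TTCCTGACTTATACGCTTACCT	.	8459	21019	21096	+	culicinae
aal-miR-new3-2*	TAAGTAGATAAATCAGAAAGA	.	8459	21019	21096	+	culicinae
aal-miR-new4	TAAGCAATTTATCGTCTTGAT	G	4828	59852	59768	-	culicinae
aal-miR-new5	AACGTGATGTATGTGAGAAGAG	.	3687	11751	11663	-	aedes
aal-miR-new6	TGTAGAAATGTTCGGATTTCGGCT	GAA	15327	62795	62885	+	aedes
aal-miR-new7	CAGGATTCGAAGTAGGTCAT	GCTA	21414	4023	3929	-	aedes
aal-miR-new8	GAGGACTAAGCGCATTTTTT	.	924	44864	44777	-	aedes
aal-miR-new9	TCCACTATTAGCCGCGAATTTGA	.	2411	9437	9370	-	aedes
aal-miR-new10	GAAGACACCGGAACGATTTGA	.	24094	20128	20040	-	aedes
aal-miR-new11	TTTGACAGTTCTGAAGATGAC	.	1075	3388	3473	+	aedes
aal-miR-new12	ATGGTACATTGAAGTAGGTGAG	.	22140	9042	8966	-	aedes
aal-miR-new13	CTTCATGATGACAACTTACACA	.	11123	34944	34853	-	aedes
aal-miR-new13*	TATGTTTGGTTCATACTGAT	.	11123	34944	34853	-	aedes
aal-miR-new14	AGGGAAGGCAGTTTGAACAGCGGG	A	25387	2495	2423	-	aedes
aal-miR-new15	AACTTTAGAAGCTTCAAGGTA	.	5127	29042	29129	+	aedes
aal-miR-new15*	GCCTTGACTGGTTTCCTGTT	.	5127	29042	29129	+	aedes
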