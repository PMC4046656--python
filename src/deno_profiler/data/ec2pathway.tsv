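# EC -> metabolic-pathway membership for the pathways of the olive
# ripe-fruit/abscission-zone comparison (KEGG-style pathway names).
# An EC code may belong to several pathways.
ec	pathway
3.2.1.26	Starch and sucrose metabolism
2.4.1.13	Starch and sucrose metabolism
3.2.1.39	Starch and sucrose metabolism
2.4.1.1	Starch and sucrose metabolism
2.4.1.12	Starch and sucrose metabolism
2.7.7.27	Starch and sucrose metabolism
2.7.7.9	Starch and sucrose metabolism
3.1.1.11	Starch and sucrose metabolism
5.1.3.6	Starch and sucrose metabolism
5.3.1.9	Starch and sucrose metabolism
3.2.1.2	Starch and sucrose metabolism
4.1.1.35	Starch and sucrose metabolism
2.4.1.21	Starch and sucrose metabolism
3.2.1.4	Starch and sucrose metabolism
2.7.1.4	Starch and sucrose metabolism
3.1.3.12	Starch and sucrose metabolism
3.2.1.1	Starch and sucrose metabolism
3.2.1.15	Starch and sucrose metabolism
3.2.1.20	Starch and sucrose metabolism
2.6.1.1	Cysteine and methionine metabolism
2.7.1.100	Cysteine and methionine metabolism
2.1.1.14	Cysteine and methionine metabolism
2.1.1.37	Cysteine and methionine metabolism
2.5.1.47	Cysteine and methionine metabolism
2.5.1.6	Cysteine and methionine metabolism
2.5.1.48	Cysteine and methionine metabolism
2.8.1.2	Cysteine and methionine metabolism
3.1.3.77	Cysteine and methionine metabolism
3.3.1.1	Cysteine and methionine metabolism
5.3.1.23	Cysteine and methionine metabolism
1.1.1.27	Cysteine and methionine metabolism
1.14.17.4	Cysteine and methionine metabolism
2.3.1.30	Cysteine and methionine metabolism
2.5.1.16	Cysteine and methionine metabolism
4.1.1.50	Cysteine and methionine metabolism
2.7.2.4	Cysteine and methionine metabolism
5.3.1.8	Amino sugar and nucleotide sugar metabolism
5.3.1.9	Amino sugar and nucleotide sugar metabolism
1.1.1.271	Amino sugar and nucleotide sugar metabolism
2.7.1.4	Amino sugar and nucleotide sugar metabolism
2.7.7.27	Amino sugar and nucleotide sugar metabolism
2.7.7.64	Amino sugar and nucleotide sugar metabolism
2.7.7.9	Amino sugar and nucleotide sugar metabolism
5.1.3.6	Amino sugar and nucleotide sugar metabolism
3.2.1.14	Amino sugar and nucleotide sugar metabolism
4.1.1.35	Amino sugar and nucleotide sugar metabolism
3.2.1.55	Amino sugar and nucleotide sugar metabolism
5.1.3.12	Amino sugar and nucleotide sugar metabolism
5.4.2.8	Amino sugar and nucleotide sugar metabolism
2.7.1.1	Glycolysis / Gluconeogenesis
2.7.1.11	Glycolysis / Gluconeogenesis
4.1.2.13	Glycolysis / Gluconeogenesis
1.2.1.12	Glycolysis / Gluconeogenesis
2.7.2.3	Glycolysis / Gluconeogenesis
5.4.2.11	Glycolysis / Gluconeogenesis
4.2.1.11	Glycolysis / Gluconeogenesis
2.7.1.40	Glycolysis / Gluconeogenesis
1.1.1.1	Glycolysis / Gluconeogenesis
5.3.1.9	Glycolysis / Gluconeogenesis
4.1.1.17	Arginine and proline metabolism
1.5.1.2	Arginine and proline metabolism
3.5.3.1	Arginine and proline metabolism
2.6.1.13	Arginine and proline metabolism
1.2.1.41	Arginine and proline metabolism
2.7.2.11	Arginine and proline metabolism
1.5.5.2	Arginine and proline metabolism
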