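# germline-version: airrkit-human-2024.1
# Curated subset of human IG/TR germline gene and allele names (IMGT nomenclature).
locus	segment	gene	alleles	functionality
TRB	V	TRBV1	01	P
TRB	V	TRBV2	01,02	F
TRB	V	TRBV3-1	01,02	F
TRB	V	TRBV4-1	01,02	F
TRB	V	TRBV4-2	01,02	F
TRB	V	TRBV4-3	01,02	F
TRB	V	TRBV5-1	01,02	F
TRB	V	TRBV5-4	01,02	F
TRB	V	TRBV5-5	01,02	F
TRB	V	TRBV5-6	01	F
TRB	V	TRBV5-8	01,02	F
TRB	V	TRBV6-1	01	F
TRB	V	TRBV6-2	01	F
TRB	V	TRBV6-3	01	F
TRB	V	TRBV6-4	01,02	F
TRB	V	TRBV6-5	01	F
TRB	V	TRBV6-6	01,02	F
TRB	V	TRBV6-8	01	F
TRB	V	TRBV6-9	01	F
TRB	V	TRBV7-2	01,02,03	F
TRB	V	TRBV7-3	01,02	F
TRB	V	TRBV7-4	01	F
TRB	V	TRBV7-6	01,02	F
TRB	V	TRBV7-7	01,02	F
TRB	V	TRBV7-8	01,02,03	F
TRB	V	TRBV7-9	01,02,03	F
TRB	V	TRBV9	01,02	F
TRB	V	TRBV10-1	01,02	F
TRB	V	TRBV10-2	01,02	F
TRB	V	TRBV10-3	01,02,03	F
TRB	V	TRBV11-1	01	F
TRB	V	TRBV11-2	01,02,03	F
TRB	V	TRBV11-3	01,02,03	F
TRB	V	TRBV12-3	01	F
TRB	V	TRBV12-4	01,02	F
TRB	V	TRBV12-5	01	F
TRB	V	TRBV13	01,02	F
TRB	V	TRBV14	01,02	F
TRB	V	TRBV15	01,02,03	F
TRB	V	TRBV16	01,02,03	F
TRB	V	TRBV18	01	F
TRB	V	TRBV19	01,02,03	F
TRB	V	TRBV20-1	01,02	F
TRB	V	TRBV21-1	01	P
TRB	V	TRBV23-1	01	ORF
TRB	V	TRBV24-1	01	F
TRB	V	TRBV25-1	01	F
TRB	V	TRBV27	01	F
TRB	V	TRBV28	01	F
TRB	V	TRBV29-1	01,02,03	F
TRB	V	TRBV30	01,02	F
TRB	D	TRBD1	01	F
TRB	D	TRBD2	01,02	F
TRB	J	TRBJ1-1	01	F
TRB	J	TRBJ1-2	01	F
TRB	J	TRBJ1-3	01	F
TRB	J	TRBJ1-4	01	F
TRB	J	TRBJ1-5	01	F
TRB	J	TRBJ1-6	01,02	F
TRB	J	TRBJ2-1	01	F
TRB	J	TRBJ2-2	01	F
TRB	J	TRBJ2-3	01	F
TRB	J	TRBJ2-4	01	F
TRB	J	TRBJ2-5	01	F
TRB	J	TRBJ2-6	01	F
TRB	J	TRBJ2-7	01,02	F
IGH	V	IGHV1-2	01,02,04	F
IGH	V	IGHV1-3	01,02	F
IGH	V	IGHV1-8	01,02	F
IGH	V	IGHV1-18	01,03,04	F
IGH	V	IGHV1-24	01	F
IGH	V	IGHV1-45	01,02	F
IGH	V	IGHV1-46	01,03	F
IGH	V	IGHV1-58	01,02	F
IGH	V	IGHV1-69	01,02,04,06	F
IGH	V	IGHV2-5	01,02	F
IGH	V	IGHV2-26	01	F
IGH	V	IGHV2-70	01,04	F
IGH	V	IGHV3-7	01,02	F
IGH	V	IGHV3-9	01	F
IGH	V	IGHV3-11	01	F
IGH	V	IGHV3-13	01	F
IGH	V	IGHV3-15	01,02	F
IGH	V	IGHV3-20	01	F
IGH	V	IGHV3-21	01,02	F
IGH	V	IGHV3-23	01,02,04	F
IGH	V	IGHV3-30	01,02,03,18	F
IGH	V	IGHV3-33	01,03	F
IGH	V	IGHV3-43	01	F
IGH	V	IGHV3-48	01,02,03	F
IGH	V	IGHV3-49	01,03	F
IGH	V	IGHV3-53	01,02	F
IGH	V	IGHV3-64	01,02	F
IGH	V	IGHV3-66	01,02	F
IGH	V	IGHV3-72	01	F
IGH	V	IGHV3-73	01,02	F
IGH	V	IGHV3-74	01,02	F
IGH	V	IGHV4-4	02,07	F
IGH	V	IGHV4-28	01,02	F
IGH	V	IGHV4-31	03	F
IGH	V	IGHV4-34	01,02	F
IGH	V	IGHV4-39	01,07	F
IGH	V	IGHV4-59	01,02	F
IGH	V	IGHV4-61	01,02	F
IGH	V	IGHV5-51	01,03	F
IGH	V	IGHV6-1	01,02	F
IGH	V	IGHV7-4-1	01,02	F
IGH	D	IGHD1-1	01	F
IGH	D	IGHD1-7	01	F
IGH	D	IGHD1-26	01	F
IGH	D	IGHD2-2	01,02	F
IGH	D	IGHD2-8	01,02	F
IGH	D	IGHD2-15	01	F
IGH	D	IGHD2-21	01,02	F
IGH	D	IGHD3-3	01,02	F
IGH	D	IGHD3-9	01	F
IGH	D	IGHD3-10	01,02	F
IGH	D	IGHD3-16	01,02	F
IGH	D	IGHD3-22	01	F
IGH	D	IGHD4-17	01	F
IGH	D	IGHD4-23	01	ORF
IGH	D	IGHD5-12	01	F
IGH	D	IGHD5-18	01	F
IGH	D	IGHD6-6	01	F
IGH	D	IGHD6-13	01	F
IGH	D	IGHD6-19	01	F
IGH	D	IGHD6-25	01	F
IGH	D	IGHD7-27	01	F
IGH	J	IGHJ1	01	F
IGH	J	IGHJ2	01	F
IGH	J	IGHJ3	01,02	F
IGH	J	IGHJ4	01,02,03	F
IGH	J	IGHJ5	01,02	F
IGH	J	IGHJ6	01,02,03	F
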