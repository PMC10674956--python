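pathway	degree_impact	betweenness_impact	closeness_impact	fdr	merit
ABC transporters	0	0	0.2	4.3423e-27	90.04878049
Protein digestion and absorption	0	0	0.26027	5.1706e-26	90.04878049
Central carbon metabolism in cancer	0	0	0.15789	5.2636e-20	88.17843178
Aminoacyl-tRNA biosynthesis	0.18557	0	0.1887	3.0666e-16	89.04243328
Mineral absorption	0.058824	0	0.16361	7.8109e-13	88.29666352
Glyoxylate and dicarboxylate metabolism	0.19318	0.005094	0.14279	2.6159e-07	65
Taurine and hypotaurine metabolism	0.27586	0	0.26261	4.1941e-07	90.04862
Cysteine and methionine metabolism	0.23301	0.17737	0.17003	0.000016837	88.72511315
Glycine, serine, and threonine metabolism	0.37647	0.14892	0.23869	0.000031504	90.03666656
Alanine, aspartate, and glutamate metabolism	0.4918	0.12764	0.1311	0.0005232	88.6812472
Ferroptosis	0.094595	0	0.16278	0.00080319	50
Sulfur metabolism	0	0	0.10345	0.00080319	36.6802727
Arginine biosynthesis	0.37143	0.067227	0.42256	0.00083089	89.70463799
Amoebiasis	0.016667	0	0.13142	0.0012241	36.7479835
Valine, leucine, and isoleucine biosynthesis	0.15385	0	0.15685	0.0016043	88
Sphingolipid metabolism	0.34426	0.11199	0.67273	0.0072172	89.00877813
Phenylalanine metabolism	0.11111	0.011281	0.076586	0.0092785	43.91079969
Purine metabolism	0.16832	0.014208	0.11081	0.010746	66.68460826
Thiamine metabolism	0.026316	0	0.11902	0.010746	36.7661384
Pantothenate and CoA biosynthesis	0.095238	0	0.1303	0.010746	36.78520447
Arginine and proline metabolism	0.1453	0.039309	0.10489	0.01168	65
Staphylococcus aureus infection	0.093023	0.0011074	0.095363	0.021438	36.83966667
Gap junction	0.076923	0	0.24965	0.021454	50
Neuroactive ligand-receptor interaction	0.061798	0	0.062116	0.023787	30.30921831
Primary bile acid biosynthesis	0.09375	0	0.23168	0.027448	50
AGE-RAGE signaling pathway in diabetic complications	0.029412	0	0.13354	0.029015	36.71982118
Tyrosine metabolism	0.1129	0.04149	0.094005	0.032855	65
Butanoate metabolism	0.16364	0.016498	0.089484	0.032855	88
Pyruvate metabolism	0.33962	0.038462	0.25425	0.032855	88.14549064
Taste transduction	0.14085	0	0.12007	0.032961	36.73783459
Nitrogen metabolism	0.065217	0	0.069877	0.036419	14.3852384
Carbohydrate digestion and absorption	0	0	0.080645	0.036419	13.94718423
Phenylalanine, tyrosine, and tryptophan biosynthesis	0.29268	0.0093496	0.085978	0.046353	50
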