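otu_id,organism,accession,similarity,AE/AE-13D,AE/AE-13B,AE/AE-13T,AE/AE-13N
OTU1,Rhodanobacter sp. D1SP217,KT183544,100,43.0,51.4,53.3,55.2
OTU2,Bradyrhizobium sp. URHE0020 / Afipia sp. K43-4AA,LN876515/KU713085,100,14.0,13.2,11.5,10.4
OTU3,Rhizobium sp. AT-BI-01,KX023855,100,11.2,13.7,10.6,8.8
OTU4,Hyphomicrobium sp. NDB2Meth4,KY621474,100,11.6,7.9,6.7,6.3
OTU5,Marinobacterium sp. Sydgv7,KC462989,89,4.1,2.7,3.6,4.2
OTU6,Mesorhizobium loti TONO,AP017605,100,2.4,2.3,3.3,2.4
OTU7,Aminobacter aminovorans LZ1304-3-1 / Mesorhizobium sp. Lot-his 2,KX881427/KX660736,100,2.4,1.9,2.7,2.9
OTU8,Mycobacterium sp. byf-4,FJ169473,100,2.1,0.7,1.1,0.9
OTU9,Parvibaculum sp. TSASRA023,KJ573556,96,1.3,1.3,1.3,2.3
OTU10,Coxiella endosymbiont of Ornithodoros sp.,KP994802,93,1.5,0.9,1.2,1.6
OTU11,Flavitalea populi HY-50R,NR_117796,99,0.2,0.3,0.7,0.8
OTU12,Pseudomonas putida F1,CP000712,100,1.6,0.4,<0.1,<0.1
OTU13,Vermamoeba vermiformis BCP-EM3VF21-2,KT185627,93,0.1,0.1,0.1,0.8
OTU14,Propioniferax sp. P7,EU109728,100,<0.1,0.2,0.3,0.4
OTU15,Pseudomonas sp. Rs81,AM905941,100,0.2,<0.1,<0.1,<0.1
OTU16,Humibacillus sp. S3SS536,KT183563,99,0.2,<0.1,<0.1,<0.1
OTU17,Unclassified Alphaproteobacteria Ellin6089,AY234741,99,0.1,0.1,<0.1,<0.1
OTU18,Paludisphaera borealis PT1,KT372165,98,0.1,<0.1,<0.1,<0.1
OTU19,Thiobacillus thioparus NZ,KC542801,100,0.1,<0.1,<0.1,<0.1
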