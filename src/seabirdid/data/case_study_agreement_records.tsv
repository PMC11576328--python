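n	date	fishery	visual_taxon	visual_rank	genetic_taxon	genetic_rank
18	02/2019	ETBF	Ardenna spp.	genus	Ardenna carneipes	species
2	04/2019	ETBF	Diomedeidae	family	Thalassarche steadi	species
1	05/2019	ETBF	Diomedea exulans	species	Thalassarche steadi	species
2	09/2019	ETBF	Diomedeidae	family	Thalassarche bulleri	species
17	10/2019	ETBF	Diomedeidae	family	Diomedea antipodensis	species
1	10/2019	ETBF	Ardenna tenuirostris	species	Ardenna carneipes	species
1	03/2020	ETBF	Thalassarche melanophris	species	Thalassarche steadi	species
2	06/2020	ETBF	Thalassarche cauta	species	Thalassarche steadi	species
1	10/2020	ETBF	Laridae	family	Sterna sp.	genus
1	06/2021	ETBF	Diomedeidae	family	Thalassarche impavida	species
3	09/2021	ETBF		none	Ardenna carneipes	species
1	10/2022	ETBF	Diomedeidae	family	Diomedea exulans	species
2	10/2022	ETBF	Ardenna carneipes	species	Ardenna carneipes	species
3	10/2022	ETBF	Procellariidae	family	Ardenna carneipes	species
1	03/2022	ETBF	Diomedea exulans	species	Diomedea antipodensis	species
3	12/2022	SESSF	Ardenna tenuirostris	species	Procellaria aequinoctialis	species
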