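# synthetic miniature municipality list, population-weighted (2019-style)
# columns: surface<TAB>weight
València	794288
Alacant	334887
Elx	232517
Castelló de la Plana	171728
Torrevieja	83337
Torrent	81245
Orihuela	77414
Gandia	74562
Paterna	70195
Benidorm	68721
Sagunt	66140
Alcoi	58977
Sant Vicent del Raspeig	57785
Elda	52404
Vila-real	50893
Mislata	43775
Burjassot	38148
Ontinyent	35347
Alzira	44938
Xàtiva	29070
Petrer	34276
Aldaia	31492
Manises	30693
Alaquàs	29474
Dénia	42166
Xirivella	29308
Catarroja	28119
Villena	33964
Quart de Poblet	24491
Paiporta	25312
Benicarló	26744
Vinaròs	28682
Picassent	20658
Godella	13256
Rocafort	7373
Bétera	23805
Llíria	22793
Riba-roja de Túria	22003
Sueca	27375
Cullera	22145
Oliva	25789
Crevillent	28957
Novelda	25725
Altea	22385
Calp	21633
Xàbia	27225
Santa Pola	31745
Requena	20317
Utiel	11524
Almassora	26066
Borriana	34683
Nules	13456
La Vall d'Uixó	31660
Segorbe	9027
Ademuz	1056
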