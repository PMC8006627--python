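# synthetic miniature given-name list, frequency-weighted
# columns: surface<TAB>weight
José	602810
Antonio	552235
Juan	500247
Manuel	498657
Francisco	455732
David	364087
María	343264
Carmen	309959
Josefa	265087
Javier	262269
Daniel	254748
Isabel	252903
Ana	243733
Jesús	229227
Carlos	226242
Miguel	220833
Dolores	210273
Pilar	205436
Alejandro	204963
Teresa	192724
Rafael	191509
Pedro	188957
Francisca	187823
Ángel	181672
Rosa	174281
José Luis	168962
Pablo	167096
Sergio	162357
Laura	159321
Antonia	156143
Luis	155384
Jorge	153432
Alberto	147633
Cristina	146279
Marta	144243
Fernando	142886
Mercedes	137931
Elena	128876
Juan Carlos	128360
Raúl	127794
Lucía	125191
Adrián	123240
Álvaro	121679
Rubén	118561
Iván	115366
Óscar	112094
Diego	110884
Enrique	109096
Andrés	106261
Concepción	104977
Sara	104213
Paula	103046
Julia	99257
Ramón	98995
Vicente	97984
Marina	92874
Víctor	92186
Silvia	90619
Ignacio	88694
Andrea	88570
Patricia	87997
Rocío	86476
Alicia	84871
Eduardo	83961
Julián	81482
Sandra	79839
Mónica	78024
Susana	77041
Yolanda	75506
Alba	74675
Beatriz	73066
Margarita	72983
Nuria	69783
Inmaculada	68935
Montserrat	66845
Esther	65761
Hugo	64917
Ainhoa	62714
Amparo	61926
Sonia	61614
Emilio	60768
Encarnación	59768
Gloria	58761
Tomás	57815
Gabriel	57161
Nerea	55424
Joaquín	54966
Eva	54705
Natalia	54179
Irene	53891
Gonzalo	52286
Salvador	51971
Verónica	50789
Claudia	49661
Aitana	48273
Xiaojing	2150
Steven	6843
Abdul	3412
Harrison	1204
Fatima	15230
Mohamed	24810
Luz	40210
Consuelo	50120
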