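# synthetic miniature surname list, frequency-weighted
# columns: surface<TAB>weight
García	1462870
González	926521
Rodríguez	925745
Fernández	917682
López	867462
Martínez	830649
Sánchez	817795
Pérez	773157
Gómez	489813
Martín	470615
Jiménez	390161
Ruiz	343499
Hernández	343163
Díaz	332858
Moreno	318330
Muñoz	267817
Álvarez	265155
Romero	251813
Alonso	222723
Gutiérrez	180889
Navarro	178956
Torres	170035
Domínguez	168228
Vázquez	160983
Ramos	157708
Gil	156193
Ramírez	147865
Serrano	143542
Blanco	129368
Molina	128956
Morales	126529
Suárez	124625
Ortega	122968
Delgado	120243
Castro	119723
Ortiz	115822
Rubio	113939
Marín	109232
Sanz	104926
Núñez	103587
Iglesias	97731
Medina	94529
Garrido	91851
Cortés	85879
Castillo	85502
Santos	85324
Lozano	83359
Guerrero	82418
Cano	81998
Prieto	81664
Méndez	79222
Cruz	77565
Calvo	74764
Gallego	74404
Vidal	73551
León	72470
Márquez	71336
Herrera	70151
Peña	69786
Flores	68766
Cabrera	67403
Campos	64970
Vega	64694
Fuentes	64013
Carrasco	63814
Díez	60718
Caballero	60499
Reyes	59684
Nieto	58980
Aguilar	58845
Pascual	58652
Herrero	57191
Santana	57066
Lorenzo	56956
Hidalgo	55955
Montero	55879
Ibáñez	54861
Giménez	54230
Ferrer	53133
Durán	52905
Vicente	52256
Benítez	51761
Mora	51359
Santiago	50734
Arias	50476
Vargas	50318
Carmona	49847
Crespo	48964
Román	48775
Pastor	48134
Soto	48111
Sáez	47791
Velasco	46971
Soler	46684
Moya	46200
Esteban	45428
Parra	44781
Bravo	44607
Gallardo	44422
Rojas	43517
Cabeza	9874
Segura	45310
Sala	26480
Cuello	8120
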