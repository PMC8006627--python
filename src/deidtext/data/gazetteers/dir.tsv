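# synthetic miniature street-address list
# columns: surface<TAB>weight
Calle Mayor 162, 3001	1
Avenida del Puerto 166, 46005	1
Calle Colón 154, 3005	1
Gran Vía Marqués del Túria 161, 46023	1
Calle de la Paz 121, 46021	1
Avenida Blasco Ibáñez 11, 46005	1
Calle San Vicente Mártir 57, 46008	1
Avenida del Cid 114, 46002	1
Calle Xàtiva 63, 12004	1
Carrer de Sagunt 140, 46018	1
Avenida Aragón 1, 3005	1
Calle Cuenca 163, 12004	1
Carrer de Russafa 14, 46025	1
Avenida Peris y Valero 128, 46021	1
Calle Quart 39, 3005	1
Carrer del Mestre Racional 132, 46015	1
Avenida de Francia 6, 46025	1
Calle Alboraya 33, 46002	1
Carrer de Sant Pau 130, 46022	1
Plaza del Ayuntamiento 14, 46025	1
Calle Guillem de Castro 94, 46005	1
Avenida Primado Reig 103, 3003	1
Carrer de Morvedre 83, 46021	1
Calle Doctor Lluch 175, 3003	1
Avenida Tres Forques 94, 46020	1
Carrer de l'Alguer 83, 46015	1
Calle Literato Azorín 125, 46010	1
Avenida Maestro Rodrigo 155, 3005	1
Calle Pintor Sorolla 85, 46005	1
Carrer dels Centelles 43, 46015	1
Avenida de la Malva-rosa 12, 46023	1
Calle Sueca 39, 46008	1
Carrer de Cavanilles 89, 46023	1
Calle General Avilés 133, 46022	1
Avenida del Oeste 138, 46025	1
Carrer de Sant Josep de Calassanç 148, 46005	1
Calle Salamanca 174, 46011	1
Avenida Burjassot 168, 46023	1
Carrer de la Reina 108, 3003	1
Calle Conde Altea 52, 46010	1
Avenida Giorgeta 143, 12004	1
Calle Padre Tomás Montañana 178, 46020	1
Carrer de Vidal de Canelles 127, 46001	1
Calle Islas Canarias 170, 46022	1
Avenida Doctor Waksman 176, 46010	1
Carrer del Progrés 59, 46001	1
Calle Campoamor 148, 46002	1
Avenida Pérez Galdós 85, 46005	1
Carrer de Dénia 52, 46005	1
Calle Micer Mascó 114, 46018	1
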