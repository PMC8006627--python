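# synthetic miniature hospital index
# columns: surface<TAB>weight
Hospital Universitari i Politècnic La Fe	100
Hospital Clínic Universitari de València	90
Hospital General Universitari de València	85
Hospital Universitari Doctor Peset	80
Hospital Arnau de Vilanova	70
Hospital Universitari de la Ribera	65
Hospital Universitari Sant Joan d'Alacant	60
Hospital General Universitari d'Alacant	75
Hospital General Universitari d'Elx	55
Hospital Universitari de Torrevieja	40
Hospital de Dénia Marina Salud	35
Hospital General de Castelló	60
Hospital de la Plana	45
Hospital de Sagunt	40
Hospital Lluís Alcanyís de Xàtiva	35
Hospital Francesc de Borja de Gandia	40
Hospital Virgen de los Lirios d'Alcoi	35
Hospital General d'Ontinyent	20
Hospital de Vinaròs	25
Hospital de Requena	15
Hospital de Manises	45
Hospital Vega Baja d'Orihuela	40
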