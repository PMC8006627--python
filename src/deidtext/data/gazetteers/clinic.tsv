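# synthetic miniature outpatient-clinic index
# columns: surface<TAB>weight
Centre de Salut de Burjassot	10
Centre de Salut Serreria I	10
Centre de Salut de Paterna	10
Centre de Salut Trinitat	8
Centre de Salut de Mislata	9
Centre de Salut de Torrent II	8
Centre de Salut d'Alaquàs	7
Centre de Salut de Catarroja	7
Centre de Salut Salvador Pau	6
Centre de Salut Benimaclet	8
Centre de Salut Nàquera	3
Centre de Salut de Godella	4
Centre de Salut Fuensanta	5
Centre de Salut de Xirivella	6
Centre de Salut Malva-rosa	6
Centre de Salut de Picassent	5
Centre de Salut República Argentina	5
Centre de Salut de Sueca	5
Centre de Salut de Cullera	4
Centre d'Especialitats de Monteolivete	4
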