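# Synthetic bank of neutral Valencian radiology filler phrases (tag O),
# used by the structurally divergent department profile.
# Numeric slots: {n} small integer, {mm} millimetres, {t} clock time.
TAC cranial sense contrast intravenós.
No s'observen alteracions significatives del parènquima cerebral.
Sistema ventricular de mida i morfologia normals.
Línia mitjana centrada.
No s'identifiquen lesions ocupants d'espai.
Sense evidència de sagnat intracranial agut.
Fossa posterior sense alteracions.
Cisternes basals lliures.
Discreta atròfia còrtico-subcortical d'acord amb l'edat.
Petites hipodensitats en substància blanca periventricular.
Lesions compatibles amb malaltia de petit vas.
Sins paranasals ben pneumatitzats.
Cel·les mastoïdals lliures.
Solcs corticals d'amplitud conservada.
No s'observen col·leccions extraaxials.
Espais subaracnoïdals de mida normal.
Es recomana control evolutiu segons clínica.
Exploració dins de límits normals.
Troballes sense canvis respecte a l'estudi previ.
No hi ha signes d'hidrocefàlia.
Tronc de l'encèfal de morfologia i senyal normals.
Sense restricció de la difusió que suggerisca isquèmia aguda.
Conclusió: no s'objectiven lesions agudes intracranials.
Pacient remés des del servei d'urgències.
Motiu de consulta: cefalea de setmanes d'evolució.
Antecedent de traumatisme cranioencefàlic lleu.
Resta d'estructures valorades sense alteracions.
Calota cranial íntegra sense lesions lítiques ni blàstiques.
Parts blanes epicranials sense troballes.
Normal.
Estable.
Preliminar.
Comparativa.
Lesió hipodensa de {mm} mm de diàmetre màxim.
S'adquireixen {n} talls axials de {mm} mm de gruix.
Exploració realitzada a les {t} hores.
Desviació de la línia mitjana de {mm} mm cap a l'esquerra.
S'administren {n} ml de contrast iodat.
Control programat en {n} mesos.
Volum estimat de {n} cc.
Escala de Fisher grau {n}.
Sèrie {n}.
Imatge {p}.
{p}
{n}
Exploració realitzada a la sala d'urgències.
Via aèria segura i permeable.
Coll femoral de densitat conservada.
Camps pulmonars inclosos sense alteracions.
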