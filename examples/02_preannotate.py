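"""Dictionary pre-annotation and the corpus-construction filters.

Pre-annotation is context-blind: it happily tags the anatomical word
"cabeza" as a name because it is also a surname.  The min-names filter then
keeps only documents with repeated person-name hits — the cheap, effective
way to select reports that really contain personal data.
"""

import deidtext as dt
from deidtext.preannotation import filter_min_names, preannotate

gazetteers = dt.builtin_gazetteers()

texts = [
    ("r1", "Paciente María García, atendida por Pedro Sánchez.\n"
           "TAC craneal sin hallazgos."),
    ("r2", "Dolor de cabeza de semanas de evolución.\n"
           "Sin otros hallazgos."),
    ("r3", "Informe del Hospital de Sagunt.\nSin datos de filiación."),
]

annotated = [preannotate(dt.Document(i, t), gazetteers) for i, t in texts]
for doc in annotated:
    tags = [(s.label, s.surface) for s in doc.spans]
    print(f"{doc.id}: {tags}")

kept = filter_min_names(annotated, min_count=2)
print("\nkept after >=2 NAME filter:", [d.id for d in kept])
# r1 survives (two real names); r2's lone ambiguous 'cabeza' hit and r3's
# institution-only content are filtered out.
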