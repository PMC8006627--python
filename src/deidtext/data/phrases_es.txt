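# Synthetic bank of neutral Spanish radiology filler phrases (tag O).
# One phrase per line; '#' lines ignored.
TAC craneal sin contraste intravenoso.
Se realiza estudio de resonancia magnética cerebral.
No se observan alteraciones significativas en el parénquima cerebral.
Sistema ventricular de tamaño y morfología normales.
Línea media centrada.
No se identifican lesiones ocupantes de espacio.
Sin evidencia de sangrado intracraneal agudo.
Fosa posterior sin alteraciones.
Estructuras de la línea media sin desplazamientos.
Cisternas basales libres.
Discreta atrofia córtico-subcortical acorde con la edad.
Pequeñas hipodensidades en sustancia blanca periventricular.
Lesiones compatibles con enfermedad de pequeño vaso.
No se aprecian realces patológicos tras la administración de contraste.
Silla turca y región selar sin hallazgos.
Senos paranasales bien neumatizados.
Ocupación mucosa del seno maxilar derecho.
Celdillas mastoideas libres.
Calcificaciones fisiológicas de plexos coroideos y pineal.
Surcos corticales de amplitud conservada.
No se observan colecciones extraaxiales.
Espacios subaracnoideos de tamaño normal.
Unión cráneo-cervical sin alteraciones.
Se recomienda control evolutivo según clínica.
Exploración dentro de límites normales.
Hallazgos sin cambios respecto a estudio previo.
Infarto lacunar crónico en ganglios basales izquierdos.
Leucoaraiosis de predominio frontal.
No hay signos de hidrocefalia.
Tronco del encéfalo de morfología y señal normales.
Hipocampos simétricos sin alteraciones de señal.
Órbitas y contenido orbitario sin hallazgos relevantes.
Ausencia de desviación significativa de la línea media.
Moderada ampliación de los espacios de Virchow-Robin.
Cambios posquirúrgicos frontales derechos estables.
Pequeño quiste aracnoideo temporal izquierdo sin efecto de masa.
Estudio angiográfico sin estenosis significativas.
Polígono de Willis permeable.
Arterias carótidas internas permeables y de calibre conservado.
Dudosa imagen hipodensa parietal que se recomienda valorar con RM.
Sin restricción de la difusión que sugiera isquemia aguda.
Secuencias de difusión sin alteraciones.
Sin captaciones patológicas de contraste paramagnético.
Quiste de retención mucosa en seno esfenoidal.
Impresión diagnóstica: estudio sin hallazgos patológicos agudos.
Conclusión: no se objetivan lesiones agudas intracraneales.
Se valorará evolución en consultas externas.
Paciente remitido desde el servicio de urgencias.
Motivo de consulta: cefalea de semanas de evolución.
Antecedente de traumatismo craneoencefálico leve.
Clínica de mareo inespecífico en estudio.
Episodio sincopal sin focalidad neurológica.
Control de lesión conocida previamente descrita.
Se completa estudio con secuencias potenciadas en T2 y FLAIR.
Artefactos de movimiento que limitan parcialmente la valoración.
Resto de estructuras valoradas sin alteraciones.
Calota craneal íntegra sin lesiones líticas ni blásticas.
Partes blandas epicraneales sin hallazgos.
Glándulas parótidas y espacios cervicales superiores normales.
No se observan adenopatías de tamaño significativo.
Los hallazgos descritos carecen de traducción clínica urgente.
Se sugiere correlación con datos analíticos.
# numeric-slot phrases: {n} small integer, {mm} millimetres, {t} time
Lesión hipodensa de {mm} mm de diámetro máximo.
Se adquieren {n} cortes axiales de {mm} mm de espesor.
Exploración realizada a las {t} horas.
Hematoma subdural crónico de {mm} mm de grosor máximo.
Desviación de línea media de {mm} mm hacia la izquierda.
Quiste aracnoideo de {mm} x {mm} mm en fosa temporal.
Se administran {n} ml de contraste yodado.
Índice de Evans de 0.{n}.
Dilatación ventricular con índice de {n} %.
Control programado en {n} meses.
Escala de Fisher grado {n}.
Se identifican {n} lesiones puntiformes subcorticales.
Tiempo de adquisición de {n} minutos.
Aneurisma sacular de {mm} mm en arteria comunicante anterior.
Calcificación puntiforme de {mm} mm parietal derecha.
Volumen estimado de {n} cc.
Normal.
Estable.
Preliminar.
Comparativa.
Sin cambios.
Serie {n}.
Imagen {p}.
{p}
{n}
Dolor de cabeza inespecífico referido por el paciente.
Cabeza del caudado de morfología conservada.
Campos pulmonares incluidos en el estudio sin alteraciones.
Reducción de la luz del vaso inferior al 50 %.
Luz del canal raquídeo conservada.
Refuerzo del pilar amigdalino derecho.
Pilares diafragmáticos sin alteraciones.
Línea alba sin defectos herniarios.
Cuello femoral de densidad conservada.
Cuerpo calloso delgado sin otras alteraciones.
Vía aérea segura y permeable.
Exploración realizada en sala de urgencias.
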