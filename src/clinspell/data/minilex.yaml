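# Mini-lexicon for the synthetic clinical-Spanish corpus generator.
# Closure by construction: for every inflectional paradigm below, all genre
# and number forms are listed, so rule-generated errors on these words are
# attested real words and the lexicon gate cannot starve a rule group.

# Invariant-gender nouns: [singular, plural, gender]
nouns:
  - [paciente, pacientes, m]
  - [dolor, dolores, m]
  - [tumor, tumores, m]
  - [valor, valores, m]
  - [calor, calores, m]
  - [control, controles, m]
  - [nivel, niveles, m]
  - [nódulo, nódulos, m]
  - [quiste, quistes, m]
  - [síntoma, síntomas, m]
  - [ganglio, ganglios, m]
  - [derrame, derrames, m]
  - [antecedente, antecedentes, m]
  - [resultado, resultados, m]
  - [fármaco, fármacos, m]
  - [tubo, tubos, m]
  - [uso, usos, m]
  - [huso, husos, m]
  - [vello, vellos, m]
  - [masa, masas, f]
  - [prueba, pruebas, f]
  - [herida, heridas, f]
  - [pared, paredes, f]
  - [señal, señales, f]
  - [molestia, molestias, f]
  - [zona, zonas, f]
  - [ecografía, ecografías, f]
  - [analítica, analíticas, f]
  - [virtud, virtudes, f]
  - [onda, ondas, f]

# Person nouns with a full genre x number paradigm (masculine singular form;
# the other three forms are derived regularly: -o -> -a, + -s).
person_nouns:
  - enfermero
  - médico
  - cirujano

# Adjectives and adjectival participles, masculine singular form. Every one
# ends in a suffix from the genre rule table; the remaining three forms are
# derived regularly.
adjectives:
  - conservado
  - elevado
  - marcado
  - moderado
  - aislado
  - localizado
  - prolongado
  - controlado
  - observado
  - realizado
  - presentado
  - mejorado
  - tolerado
  - unido
  - disminuido
  - definido
  - recibido
  - sufrido
  - respondido
  - persistido
  - crónico
  - típico
  - quístico
  - doloroso
  - edematoso
  - fibroso
  - urinario
  - coronario
  - purulento
  - sanguinolento
  - femenino
  - masculino

# Regular verbs: [infinitive, conjugation class]. All 36 regular forms
# (3 tenses x 2 moods x 6 persons) of each verb are added to the lexicon.
verbs:
  - [presentar, ar]
  - [realizar, ar]
  - [llevar, ar]
  - [mejorar, ar]
  - [tolerar, ar]
  - [controlar, ar]
  - [observar, ar]
  - [evolucionar, ar]
  - [pelear, ar]
  - [responder, er]
  - [beber, er]
  - [deber, er]
  - [toser, er]
  - [sufrir, ir]
  - [recibir, ir]
  - [persistir, ir]

# Additional homophone-bearing words so the silent-h and b/v rules can pass
# the lexicon gate (each member of a pair is itself a real Spanish word).
homophones:
  - hecho
  - echo
  - haya
  - halla
  - tuvo
  - bello
  - basta
  - vasta
  - hasta
  - asta
  - honda

# Glue words used by the sentence templates (most are also on the skip
# list, so errors are not planted on them, but they belong in the lexicon).
function_words:
  - el
  - la
  - los
  - las
  - un
  - una
  - de
  - del
  - al
  - en
  - con
  - sin
  - por
  - tras
  - se
  - "no"
  - y
  - a
  - ha
  - es
  - son
  - está
  - están
  - fue
  - muy
  - bien
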