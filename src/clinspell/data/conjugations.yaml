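# Regular Spanish verb terminations by conjugation class, tense and mood.
# Person slots are 1..6 = yo, tú, él/ella, nosotros, vosotros, ellos/ellas.
# "past" is the imperfect paradigm (-aba / -ía); accented endings keep their
# accents, so e.g. pelear: peleaba -> peleábamos is a distance-5 indel swap.
classes:
  ar:
    infinitive_ending: ar
    terminations:
      present:
        indicative: [o, as, a, amos, áis, an]
        subjunctive: [e, es, e, emos, éis, en]
      past:
        indicative: [aba, abas, aba, ábamos, abais, aban]
        subjunctive: [ara, aras, ara, áramos, arais, aran]
      future:
        indicative: [aré, arás, ará, aremos, aréis, arán]
        subjunctive: [are, ares, are, áremos, areis, aren]
  er:
    infinitive_ending: er
    terminations:
      present:
        indicative: [o, es, e, emos, éis, en]
        subjunctive: [a, as, a, amos, áis, an]
      past:
        indicative: [ía, ías, ía, íamos, íais, ían]
        subjunctive: [iera, ieras, iera, iéramos, ierais, ieran]
      future:
        indicative: [eré, erás, erá, eremos, eréis, erán]
        subjunctive: [iere, ieres, iere, iéremos, iereis, ieren]
  ir:
    infinitive_ending: ir
    terminations:
      present:
        indicative: [o, es, e, imos, ís, en]
        subjunctive: [a, as, a, amos, áis, an]
      past:
        indicative: [ía, ías, ía, íamos, íais, ían]
        subjunctive: [iera, ieras, iera, iéramos, ierais, ieran]
      future:
        indicative: [iré, irás, irá, iremos, iréis, irán]
        subjunctive: [iere, ieres, iere, iéremos, iereis, ieren]
# Full conjugation of the auxiliary "haber"; person swaps stay inside one
# tense/mood row.
haber:
  present:
    indicative: [he, has, ha, hemos, habéis, han]
    subjunctive: [haya, hayas, haya, hayamos, hayáis, hayan]
  past:
    indicative: [había, habías, había, habíamos, habíais, habían]
    subjunctive: [hubiera, hubieras, hubiera, hubiéramos, hubierais, hubieran]
  future:
    indicative: [habré, habrás, habrá, habremos, habréis, habrán]
    subjunctive: [hubiere, hubieres, hubiere, hubiéremos, hubiereis, hubieren]
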