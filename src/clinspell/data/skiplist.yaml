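# High-frequency function words ignored by the error generator so that
# errors are not planted on the same determiners and prepositions over and
# over. Matching is case-insensitive. User-extensible.
skip_list:
  # determiners / articles
  - el
  - la
  - los
  - las
  - un
  - una
  - unos
  - unas
  - lo
  - al
  - del
  - este
  - esta
  - estos
  - estas
  - ese
  - esa
  - esos
  - esas
  - aquel
  - aquella
  - aquellos
  - aquellas
  - mi
  - mis
  - tu
  - tus
  - su
  - sus
  - nuestro
  - nuestra
  - nuestros
  - nuestras
  # prepositions
  - a
  - ante
  - bajo
  - con
  - contra
  - de
  - desde
  - durante
  - en
  - entre
  - hacia
  - hasta
  - mediante
  - para
  - por
  - según
  - sin
  - sobre
  - tras
  # frequent clitics / conjunctions
  - se
  - "no"
  - y
  - e
  - o
  - u
  - que
  - como
  - más
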