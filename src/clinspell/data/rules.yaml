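# Morphological rule tables for real-word error synthesis.
# genre_suffixes are masculine singular forms; the feminine counterpart is
# obtained by replacing the final -o with -a, and plural counterparts by
# appending -s. Inverse (feminine -> masculine) rules are derived in code.
genre_suffixes: [ero, ano, ado, ino, ido, ico, ito, oso, ario, ento, olo]

number:
  # singular endings that pluralize by adding -s
  vowel_endings: [o, e, a]
  # singular endings that pluralize by adding -es
  consonant_endings: [d, n, l, j, r]
  # recognized plural endings (for the plural -> singular direction)
  plural_endings: [os, es, as]

homophone:
  # sound-identical spelling swaps, applied in both directions
  swaps:
    - [ll, y]
    - [b, v]
  # silent-h contexts: word-initial, and after these letters
  h_after: [n, s]
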