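# Absolutist dictionary, French translation (19 terms; synthetic stand-in
# list with the published structure: exactly two accented terms,
# "complètement" and "déjà", which accent-variant expansion doubles to give
# 21 query series).
absolument
tout
toute
tous
toujours
complet
complètement
constant
constamment
certainement
entier
déjà
chaque
chacun
plein
jamais
rien
totalement
total
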