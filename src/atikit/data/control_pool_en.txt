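# Pool of neutral, diacritic-free words for random-word control series
# (matched across English/French extraction; synthetic stand-in pool seeded
# with the printed examples "position", "money", "seed").
position
money
seed
table
garden
window
train
bridge
paper
bottle
river
mountain
orange
market
village
station
pocket
branch
carpet
ladder
mirror
pencil
basket
camera
candle
button
copper
desert
engine
fabric
guitar
hammer
island
jacket
kitchen
lantern
magnet
napkin
ocean
palace
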