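variant,canonical
behaviour,behavior
behaviours,behaviors
practise,practice
practised,practiced
neighbour,neighbor
neighbours,neighbors
colour,color
colours,colors
centre,center
centres,centers
mobilise,mobilize
mobilised,mobilized
organise,organize
organised,organized
realise,realize
recognise,recognize
favourite,favorite
programme,program
litre,liter
metre,meter
oedema,edema
paralyse,paralyze
analyse,analyze
analysed,analyzed
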