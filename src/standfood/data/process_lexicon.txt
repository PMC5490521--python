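# Nature-changing process lemmas, one per line. Seeded with canning,
# smoking, frying and baking plus common cooking/preservation processes;
# extend or replace with the full official process list as needed.
bake
blanch
boil
braise
brew
broil
can
candy
concentrate
cook
cure
dehydrate
distill
dry
ferment
freeze
fry
grill
grind
malt
marinate
mash
mill
mince
pasteurize
pickle
poach
powder
press
roast
salt
simmer
smoke
steam
sterilize
stew
tin
toast
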