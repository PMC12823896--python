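# Negation cues (apostrophe-free surface forms, as normalization produces).
# Must be disjoint from the valence lexicon keys.
not
no
never
none
nothing
nobody
neither
nor
without
dont
doesnt
didnt
cant
cannot
couldnt
wont
wouldnt
shouldnt
isnt
wasnt
arent
werent
aint
hardly
rarely
seldom
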