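# Default depression word list: lowercase, apostrophe-free surface forms that
# survive text normalization unchanged. One word per line; '#' starts a comment.
# Fully overridable at run time with any user-supplied lexicon file.
hopeless
afraid
useless
sad
sadness
depressed
depression
worthless
empty
alone
lonely
loneliness
tired
exhausted
miserable
despair
hopelessness
helpless
anxious
anxiety
fear
crying
cried
cry
grief
guilt
guilty
ashamed
shame
numb
pain
hurt
suffering
burden
trapped
stuck
pointless
failure
failed
broken
lost
dark
darkness
heavy
insomnia
sleepless
restless
worried
worry
dread
hollow
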