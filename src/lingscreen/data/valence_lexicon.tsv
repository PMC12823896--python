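# Default token valence lexicon: token<TAB>valence in [-4, +4].
# Lowercase, apostrophe-free surface forms. '#' starts a comment.
good	1.9
great	3.1
happy	2.7
love	3.2
loved	2.9
wonderful	2.7
nice	1.8
enjoy	2.0
enjoyed	2.3
fun	2.3
glad	2.0
hope	1.9
hopeful	2.3
calm	1.3
relaxed	1.8
better	1.9
best	3.2
fine	0.8
okay	0.9
excited	2.2
proud	2.1
grateful	2.3
beautiful	2.9
laugh	2.2
smile	2.1
comfort	1.5
comfortable	1.7
peaceful	2.2
positive	2.1
strong	1.7
bad	-2.5
sad	-2.1
terrible	-2.1
awful	-2.0
horrible	-2.5
hate	-2.7
hated	-3.2
angry	-2.3
upset	-1.8
hopeless	-2.5
worthless	-2.7
useless	-1.8
miserable	-2.6
depressed	-2.3
lonely	-2.0
alone	-1.0
afraid	-2.2
scared	-2.2
fear	-2.2
anxious	-1.9
nervous	-1.6
worried	-1.7
worry	-1.7
tired	-1.3
exhausted	-1.8
hurt	-2.1
pain	-2.3
painful	-2.4
cry	-2.0
crying	-2.2
guilty	-2.2
ashamed	-2.1
empty	-1.4
numb	-1.2
stress	-1.8
stressed	-2.0
struggle	-1.7
struggling	-1.9
difficult	-1.5
hard	-0.4
worse	-2.1
worst	-3.1
failure	-2.4
failed	-2.0
broken	-1.9
dark	-1.1
heavy	-0.6
trapped	-2.0
helpless	-2.2
despair	-2.9
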