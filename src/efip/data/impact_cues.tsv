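# Causal impact cues: cue phrase -> polarity of the stated PPI event.
# Polarity is about the PPI event itself: a facilitated dissociation is an
# increase of a dissociation event.  Editable; unknown cues found in text
# default to "unspecified".
facilitates	increase
facilitate	increase
facilitated	increase
facilitating	increase
promotes	increase
promote	increase
promoted	increase
promoting	increase
enhances	increase
enhance	increase
enhanced	increase
enhancing	increase
increases	increase
increase	increase
increased	increase
increasing	increase
induces	increase
induce	increase
induced	increase
inducing	increase
augments	increase
augmented	increase
stimulates	increase
stimulated	increase
enables	increase
enabled	increase
triggers	increase
triggered	increase
potentiates	increase
potentiated	increase
stabilizes	increase
stabilized	increase
accelerates	increase
is required for	increase
required for	increase
is necessary for	increase
is essential for	increase
abolishes	decrease
abolish	decrease
abolished	decrease
prevents	decrease
prevent	decrease
prevented	decrease
impairs	decrease
impair	decrease
impaired	decrease
reduces	decrease
reduce	decrease
reduced	decrease
reducing	decrease
decreases	decrease
decrease	decrease
decreased	decrease
decreasing	decrease
inhibits	decrease
inhibit	decrease
inhibited	decrease
disrupts	decrease
disrupt	decrease
disrupted	decrease
blocks	decrease
blocked	decrease
suppresses	decrease
suppressed	decrease
diminishes	decrease
diminished	decrease
attenuates	decrease
attenuated	decrease
abrogates	decrease
abrogated	decrease
destabilizes	decrease
destabilized	decrease
interferes with	decrease
results in	unspecified
result in	unspecified
resulted in	unspecified
resulting in	unspecified
results from	unspecified
leads to	unspecified
lead to	unspecified
led to	unspecified
leading to	unspecified
causes	unspecified
caused	unspecified
affects	unspecified
affected	unspecified
alters	unspecified
altered	unspecified
modulates	unspecified
modulated	unspecified
regulates	unspecified
regulated	unspecified
mediates	unspecified
mediated	unspecified
is important for	unspecified
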