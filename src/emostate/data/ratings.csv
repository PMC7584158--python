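# Affective-rating table shipped with emostate.
# 'happy' and 'angry' are the two ANEW rows published in the affective-norms
# literature; every other row is a SYNTHETIC vocabulary word with invented
# PAD ratings, chosen only so that all six dominant-dimension states are
# reachable. They are NOT ANEW norms.
emotion,p,a,d
happy,8.47,6.05,7.21
angry,2.53,6.2,4.11
content,7.8,4.2,6.0
calm,7.6,2.8,6.4
sad,1.8,4.4,3.2
frustrated,2.2,6.0,3.8
sleepy,6.0,1.8,4.6
bored,4.2,1.6,4.8
excited,7.0,8.6,6.2
alert,6.4,7.8,6.6
helpless,3.4,5.8,1.6
confident,6.8,5.6,8.4
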