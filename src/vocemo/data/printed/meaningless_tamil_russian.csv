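true_emotion,joy,neutral,sadness,anger
joy,67,17,11,5
neutral,19,70,11,0
sadness,14,23,62,1
anger,10,6,0,84
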