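true_emotion,joy,neutral,sadness,anger
joy,87.5,7.5,5,0
neutral,7.5,85,2.5,5
sadness,5,7.5,87.5,0
anger,2.5,5,2.5,90
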