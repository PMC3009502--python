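>A
1 -6 4 -3 5 -2
>B
3 1 -4 6 -5 2
>C
-1 -5 -4 -2 -6 3
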