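10
PA1 4
PA2.1 PA2.2 PA3.1 PA3.2
PA2.1 3
PA1 PA2.2 PA4
PA2.2 3
PA1 PA2.1 PA3.2
PA3.1 3
PA1 PA3.2 PA3.3
PA3.2 4
PA1 PA2.2 PA3.1 PA3.3
PA3.3 4
PA3.1 PA3.2 PA4 PA5.1
PA4 4
PA2.1 PA3.3 PA5.1 PA5.2
PA5.1 3
PA3.3 PA4 PA5.2
PA5.2 3
PA4 PA5.1 PA5.3
PA5.3 1
PA5.2
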