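name	class	anchor
IGHV1-7*01	V	289
IGHV1-26*01	V	283
IGHV1-82*01	V	286
IGHV2-2*01	V	289
IGHV3-6*01	V	288
IGHV5-17*01	V	282
IGHV6-3*01	V	282
IGHV9-3*01	V	286
IGHJ1*01	J	10
IGHJ2*01	J	12
IGHJ3*01	J	9
IGHJ4*01	J	9
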