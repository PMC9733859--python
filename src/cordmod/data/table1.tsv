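symptom	I2	II1	II2	II4
NIGHT BLINDNESS	yes	no	no	yes
NARROWING OF VISUAL FIELD	no	no	no	no
PHOTOPHOBIA	yes	yes	yes	yes
GREEN->LIGHT BLUE	yes	yes	no	no
WHITE PERCEPTION	no	yes	no	no
RED->ORANGE	no	no	yes	yes
BILATERAL AND HORIZONTAL NYSTAGMUS	yes	yes	yes	yes
HEAD MOVEMENT	yes	no	yes	no
PHOTOPSIA	yes	yes	no	no
BEST CONDITION DARKNESS	no	no	yes	no
PERIMACULAR INVOLVEMENT	yes	no	no	no
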