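;;; 50-word assistive vocabulary (CMUdict-format pronunciations)
AM  AE1 M
ARE  AA1 R
BAD  B AE1 D
BRING  B R IH1 NG
CLEAN  K L IY1 N
CLOSER  K L OW1 S ER0
COMFORTABLE  K AH1 M F ER0 T AH0 B AH0 L
COMFORTABLE(2)  K AH1 M F T ER0 B AH0 L
COMING  K AH1 M IH0 NG
COMPUTER  K AH0 M P Y UW1 T ER0
DO  D UW1
FAITH  F EY1 TH
FAMILY  F AE1 M AH0 L IY0
FEEL  F IY1 L
GLASSES  G L AE1 S AH0 Z
GOING  G OW1 IH0 NG
GOOD  G UH1 D
GOODBYE  G UH2 D B AY1
HAVE  HH AE1 V
HELLO  HH AH0 L OW1
HELLO(2)  HH EH0 L OW1
HELP  HH EH1 L P
HERE  HH IY1 R
HOPE  HH OW1 P
HOW  HH AW1
HUNGRY  HH AH1 NG G R IY0
I  AY1
IS  IH1 Z
IT  IH1 T
LIKE  L AY1 K
MUSIC  M Y UW1 Z IH0 K
MY  M AY1
NEED  N IY1 D
NO  N OW1
NOT  N AA1 T
NURSE  N ER1 S
OKAY  OW2 K EY1
OUTSIDE  AW1 T S AY1 D
PLEASE  P L IY1 Z
RIGHT  R AY1 T
SUCCESS  S AH0 K S EH1 S
TELL  T EH1 L
THAT  DH AE1 T
THEY  DH EY1
THIRSTY  TH ER1 S T IY0
TIRED  T AY1 ER0 D
UP  AH1 P
VERY  V EH1 R IY0
WHAT  W AH1 T
WHERE  W EH1 R
YES  Y EH1 S
YOU  Y UW1
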