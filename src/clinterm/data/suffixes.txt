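# Strippable endings approximating Polish nominal/adjectival case and
# derivation suffixes, used by the stemmer before approximate matching.
# Longest applicable suffix is removed once; ordering in this file is
# immaterial (length decides).
ościach
ościami
owego
owemu
owych
owymi
ością
ości
iego
iemu
igo
imi
ymi
ych
ich
ach
ami
owi
owie
ego
emu
em
om
ów
ie
ia
iu
ią
ię
io
yj
ij
ej
ą
ę
y
i
e
a
u
o
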