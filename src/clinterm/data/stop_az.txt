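# Modifier lemmas barred from opening a term candidate (AZ class).
aktualny
daleki
gdy
pewien
wzgląd
ten
inny
sam
niektóry
wczesny
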