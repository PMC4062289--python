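# Noun lemmas barred from opening a term candidate (NZ class):
# pronominal/introductory nouns, time and duration words, month and
# weekday names.  Editable; one lemma per line.
to
co
obrąb
kierunek
cel
czas
możliwość
podstawa
ciąg
cecha
trakt
okres
chwila
moment
termin
dzień
doba
tydzień
miesiąc
rok
godzina
minuta
początek
koniec
przebieg
powód
wzgląd
styczeń
luty
marzec
kwiecień
maj
czerwiec
lipiec
sierpień
wrzesień
październik
listopad
grudzień
poniedziałek
wtorek
środa
czwartek
piątek
sobota
niedziela
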