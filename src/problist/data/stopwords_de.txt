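# German function words removed before stemming.
# One token per line; lines starting with '#' are comments.
aber
alle
als
also
am
an
auch
auf
aus
bei
beim
bis
das
dem
den
der
des
die
durch
ein
eine
einem
einen
einer
eines
für
im
in
ist
mit
nach
nicht
noch
ohne
oder
seit
sind
über
um
und
unter
vom
von
vor
wegen
wie
zu
zum
zur
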