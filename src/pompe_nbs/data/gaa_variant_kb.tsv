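# GAA variant knowledge base, transcript NM_000152.3 (GRCh37).
# Classifications as curated by the reporting screening program.
# Keys are whitespace-normalized spellings except where a verbatim printed
# spelling (internal space preserved) carries its own classification.
# Spellings lacking the "c." prefix are verbatim report spellings kept
# distinct from their prefixed forms on purpose.
hgvs_c	classification
c.-32-13T>G	pathogenic
c.-32-13T>C	pathogenic
c.759delC	pathogenic
c.1551+1G>C	pathogenic
c.525delT	pathogenic
c.1694_1697delTCTC	pathogenic
c.2238G>C	pathogenic
c.1552-3C>G	pathogenic
c.546 G>A	pathogenic
c.1655T>C	pathogenic
c.2281delGinsAT	pathogenic
c.1438-1G>C	pathogenic
c.2560C>T	pathogenic
c.156_157delTC	pathogenic
c.456_458insGA	pathogenic
c.1856G>A	pathogenic
c.1441T>C	pathogenic
c.1547G>A	pathogenic
c.1A>G	pathogenic
c.2236T>C	pathogenic
c.1478C>T	pathogenic
c.784G>A	pathogenic
c.2105G>T	pathogenic
c.258dupC	pathogenic
c.1504A>G	pathogenic
c.692+3G>C	vus
c.1594G>A	vus
c.546G>A	vus
c.266G>A	vus
c.1377C>G	vus
c.2003A>G	vus
c.1721T>C	vus
c.1291_1299del9	vus
1655T>C	vus
c.533G>A	vus
c.862G>A	vus
c.841C>T	vus
c.1345C>T	vus
c.1888+5G>T	vus
c.700A>G/C	vus
1194+3G>C	vus
c.1392G>C	vus
c.1124G>A	vus
c.705G>A	vus
c.650C>T	vus
c.664G>A	vus
c.1103G>A	vus
c.1909C>A	vus
c.1378G>A	vus
c.2467A>T	vus
c.726G>A	vus
c.2065G>A	pseudodeficiency
c.271G>A	pseudodeficiency
c.1726G>A	pseudodeficiency
c.859-19G>A	likely_benign
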