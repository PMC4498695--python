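proband_id	variant_id	zygosity
QT058	ABCA4:c.6173T>G	het
QT058	ABCA4:c.4773+1G>T	het
QT085	ABCA4:c.6173T>G	het
QT085	ABCA4:c.5932delA	het
QT292	ABCA4:c.6389T>A	het
QT292	ABCA4:c.6118C>T	het
QT302	ABCA4:c.6816+1G>A	het
QT302	ABCA4:c.4555delA	het
QT398	ABCA4:c.4352+1G>A	het
QT398	ABCA4:c.1804C>T	het
QT431	ABCA4:c.5646G>A	het
QT431	ABCA4:c.1804C>T	het
QT458	ABCA4:c.4555delA	het
QT458	ABCA4:c.164A>G	het
QT727	ABCA4:c.161-2A>G	het
QT727	ABCA4:c.101_106del	het
QT833	ABCA4:c.2424C>G	het
QT833	ABCA4:c.1560delG	het
QT1137	ABCA4:c.6284A>T	het
QT1137	ABCA4:c.22C>T	het
QT1160	ABCA4:c.240_241del	het
QT1160	ABCA4:c.101_106del	het
QT1175	ABCA4:c.4195G>T	het
QT1175	ABCA4:c.2894A>G	het
QT1182	ABCA4:c.4773+1G>T	hom
QT1198	ABCA4:c.5646G>A	het
QT1198	ABCA4:c.2894A>G	het
QT1200	ABCA4:c.6563T>C	het
QT1200	ABCA4:c.858+2T>A	het
QT1230	ABCA4:c.6317G>C	het
QT1230	ABCA4:c.101_106del	het
QT1277	ABCA4:c.6479+2T>C	het
QT1277	ABCA4:c.5196+1G>A	het
QT1317	ABCA4:c.5646G>A	het
QT1317	ABCA4:c.4622T>C	het
MD19	ABCA4:c.4793C>G	het
MD19	ABCA4:c.634C>T	het
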