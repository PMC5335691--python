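record_id	taxon	group	pattern	role
KU350630.1	Callianassa ceramica	Axiidea	Ax2	ingroup
KU362925.1	Callianassa ceramica	Axiidea	Ax2	ingroup
NC_020025.1	Corallianassa coutierei	Axiidea	Ax1	ingroup
NC_020351.1	Nihonotrypaea japonica	Axiidea	Ax1	ingroup
NC_019610.1	Nihonotrypaea thermophila	Axiidea	Ax1	ingroup
NC_024651.1	Paraglypturus tonganus	Axiidea	Ax1	ingroup
KM501040.2	Trypaea australiensis	Axiidea	Ax2	ingroup
NC_019609.1	Neaxius acanthus	Axiidea	Ax1	ingroup
NC_019608.1	Thalassina kelanang	Gebiidea	Gr	ingroup
NC_019606.1	Austinogebia edulis	Gebiidea	Up	ingroup
NC_019607.1	Upogebia major	Gebiidea	Up	ingroup
NC_020023.1	Upogebia pusilla	Gebiidea	Up	ingroup
NC_025943.1	Upogebia yokoyai	Gebiidea	Up	ingroup
NC_018778.1	Alvinocaris chelys	Caridea	Gr	ingroup
NC_020313.1	Alvinocaris longirostris	Caridea	Gr	ingroup
NC_021971.1	Nautilocaris saintlaurentae	Caridea	Gr	ingroup
NC_020311.1	Opaepele loihi	Caridea	Gr	ingroup
NC_027116.1	Rimicaris exoculata	Caridea	Gr	ingroup
NC_020310.1	Rimicaris kairei	Caridea	Gr	ingroup
NC_014883.1	Alpheus distinguendus	Caridea	Ap1	ingroup
KP276147.1	Alpheus lobidens	Caridea	Ap2	ingroup
NC_024751.1	Caridina gracilipes	Caridea	Gr	ingroup
KU726823.1	Caridina cf. nilotica	Caridea	Gr	ingroup
NC_008413.1	Halocaridina rubra	Caridea	Gr	ingroup
NC_023823.1	Neocaridina denticulata	Caridea	Gr	ingroup
NC_027603.1	Paratya australiensis	Caridea	Gr	ingroup
KM978918.1	Macrobrachium bullatum	Caridea	Gr	ingroup
NC_012217.1	Macrobrachium lanchesteri	Caridea	Gr	ingroup
NC_015073.1	Macrobrachium nipponense	Caridea	Gr	ingroup
NC_006880.1	Macrobrachium rosenbergii	Caridea	Gr	ingroup
NC_012566.1	Palaemon carinicauda	Caridea	Pa	ingroup
NC_029240.1	Palaemon gravieri	Caridea	Pa	ingroup
NC_027601.1	Palaemon serenus	Caridea	Pa	ingroup
NC_017600.1	Acetes chinensis	Dendrobranchiata	Gr	outgroup
NC_012738.1	Farfantepenaeus californiensis	Dendrobranchiata	Gr	outgroup
NC_009679.1	Fenneropenaeus chinensis	Dendrobranchiata	Gr	outgroup
NC_026884.1	Fenneropenaeus merguiensis	Dendrobranchiata	Gr	outgroup
NC_026885.1	Fenneropenaeus penicillatus	Dendrobranchiata	Gr	outgroup
NC_009626.1	Litopenaeus vannamei	Dendrobranchiata	Gr	outgroup
NC_007010.1	Marsupenaeus japonicas	Dendrobranchiata	Gr	outgroup
NC_029457.1	Metapenaeopsis dalei	Dendrobranchiata	Gr	outgroup
NC_026834.1	Metapenaeus ensis	Dendrobranchiata	Gr	outgroup
NC_030277.1	Parapenaeopsis hardwickii	Dendrobranchiata	Gr	outgroup
NC_002184.1	Penaeus monodon	Dendrobranchiata	Gr	outgroup
NC_030280.1	Solenocera crassicornis	Dendrobranchiata	Gr	outgroup
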