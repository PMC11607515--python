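sample_id	group	Gensini	Syntax	cTnI	TIMI
S001	HC	6.747348278715974	7.158162023706679	0.016146665217171265	0.6865400750895109
S002	HC	7.634426087352766	8.953211850425895	0.029152180489904825	0.6531166168249352
S003	HC	5.405617514735603	13.384376871144893	0.03576831812380373	0.7175632343947781
S004	HC	8.054319907723098	4.562680873023556	0.02804016528070611	1.5151039214785063
S005	HC	4.8010425306699815	3.5225571369110082	0.03231177494116692	1.014764956530209
S006	HC	10.995105792167069	6.251240451248335	0.10078532641283905	0.910690441556662
S007	SCAD	43.522141849707495	17.623470013030616	0.537661485002926	3.4254010842954545
S008	SCAD	66.52265180994785	14.848805190702064	1.2409078784137384	1.4517230035755688
S009	SCAD	50.08048694010458	10.891439503651394	1.659498909865293	1.0353826450207975
S010	SCAD	37.133262451029765	12.393206573890723	2.5466751550319713	1.0783416586972885
S011	SCAD	36.450467161402145	18.012560584755843	1.8367067432597224	2.2534052218570273
S012	SCAD	38.725095357858585	9.31389522942801	1.3015041334746495	2.0726148105250304
S013	MI	51.17741619232091	39.49561584482128	0.9546017527572808	3.606131691025363
S014	MI	38.10296229636674	93.48830018957788	2.189417009315932	1.8505793508527786
S015	MI	41.37992859223774	15.810533766583863	5.227987963067488	3.4517687759845614
S016	MI	64.83867922346523	23.43951133716201	3.517872179679648	1.43119242598748
S017	MI	53.21617242100097	29.569368150357292	3.5308750426494555	1.4156001106767966
S018	MI	79.634923709761	26.789082073960877	1.6108501109666922	1.9386931810324337
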