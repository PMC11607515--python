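feature_id	S001	S002	S003	S004	S005	S006	S007	S008	S009	S010	S011	S012	S013	S014	S015	S016	S017	S018
sp001	0.013145015759712724	0.010162251881442323	0.017093662431146576	0.01627927239848188	0.0009585414768486331	0.004451652781339372	0.0027019380898098584	0.01632603340733968	0.01412276191884341	0.008303573914242048	0.006969211009802079	0.004525307260272693	0.03176274145593032	0.003919613240721362	0.00532303310478803	0.008124025405795212	0.004254735512384019	0.004997086675260932
sp002	0.024934777052507892	0.007149843066744653	0.19028466850714146	0.007542437515042148	0.031449968045479865	0.014873442417511288	0.13778475232342244	0.010292366775101246	0.09337884854140614	0.114920109813426	0.1582383372317706	0.0078442471605966	0.055852668298334275	0.021582260897214357	0.003961406515084033	0.03297123742231268	0.043875153897804046	0.05640261067319605
sp003	0.05720317410742835	0.016196581309845113	0.139123002538338	0.05434972213114541	0.11579866050941243	0.017305217081303052	0.11064377589740947	0.07643047992753073	0.3470666238246652	0.17339267623594737	0.040021383157752825	0.12493424728843906	0.06584122537559461	0.10365871799264093	0.13291645843535965	0.17737653595974898	0.07107391351695229	0.09265461703328634
sp004	0.09576360282125912	0.06226208658501275	0.065814784020107	0.010214903021063199	0.0422489758854057	0.1542133110326339	0.03945986301375001	0.09855883017240354	0.08420891067921249	0.08687331754445633	0.18502738580656478	0.043213551398292326	0.08263345194771247	0.032919992553559	0.07881930000683805	0.18575025569277528	0.0640898691838467	0.13978443764762855
sp005	0.07691754460853359	0.006063256239414652	0.01323305599684106	0.002120473436881144	0.008799724542218036	0.05048315237232067	0.019401244523519132	0.16827910843377572	0.10895947386479032	0.09980728797558745	0.14850697085032724	0.05475450378063002	0.04973741461917519	0.039131054205250815	0.053042333070445445	0.005366775024557058	0.019260220473733006	0.05677313603091096
sp006	0.031878318468110275	0.04303926147821399	0.07517695076555522	0.024644758164206863	0.559319785759723	0.04945121071876671	0.017444138952581963	0.10174594401756225	0.017226058858266325	0.05971379239176388	0.06874604670844729	0.048263119970128145	0.08455659335138668	0.04540235361980126	0.07557213566411551	0.06311826333508985	0.22133954406215955	0.04226803300833587
sp007	0.346941179090894	0.8327758326818432	0.2984506259508515	0.7483548704997973	0.12741778390294875	0.5307133634296323	0.3489968617312008	0.10721250251792654	0.08958426228592968	0.11761246298646662	0.08594270492881412	0.2807103316832621	0.2641352896839561	0.3957266942559431	0.3830151236651318	0.07266307585666824	0.4671497424768991	0.35014853479263663
sp008	0.03757566195136989	0.00030183608312449816	0.0102870673170366	0.00463470899975269	0.02279775154225663	0.019578493485727478	0.0021075717233831706	0.15967877945794523	0.023223333394884547	0.03657673812217185	0.005715318224521237	0.00907681438421824	0.008641590707134725	0.01684722729735729	0.005719154046941561	0.008641443469832956	0.005235926978052638	0.003200453294486088
sp009	0.01821664102193845	0.0022790644672898716	0.025585094209500534	0.08186556310665874	0.05443978840950465	0.04269157927254498	0.22345344621398447	0.056681612229134835	0.03844702059145765	0.09998530426451469	0.10925216411881336	0.0880139168244378	0.01354336423704297	0.03976522427397238	0.14424025588400233	0.004789071709126016	0.04338184127960047	0.1925520591282056
sp010	0.06316025941415834	0.0007555482451411107	0.08736147578989759	0.008906914018854073	0.005398290059386035	0.05866130470073472	0.058997055674937446	0.07102620595671204	0.10189015097337226	0.07858021929848688	0.031007284570531066	0.0357448453856643	0.05417451490449412	0.06955568482323432	0.01859958978890603	0.04864322097530619	0.006608266137614071	0.014034039494648142
sp011	0.2255919490550685	0.005087902506129233	0.06423432346222015	0.03837982779550226	0.016256831803380584	0.0439635133489773	0.011863134586199671	0.03940886837249086	0.021151316727063676	0.0676852447201048	0.10708194887940913	0.06068604644895007	0.13769895481135588	0.1998883332619951	0.028141005904976195	0.3328094069863896	0.01894486402582924	0.0200212361098549
sp012	0.008671876649018636	0.01392653545579875	0.013355289011364225	0.002706548912614307	0.015113898063435606	0.013613759358508368	0.027146217269801456	0.09435926873207737	0.06074123834010832	0.056549272732831876	0.05349124451324616	0.24223306841510855	0.15142219060788273	0.03160284357831015	0.07065020391341119	0.05974668816239798	0.034785922455124796	0.027163756111549777
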