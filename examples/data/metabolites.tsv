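feature_id	S001	S002	S003	S004	S005	S006	S007	S008	S009	S010	S011	S012	S013	S014	S015	S016	S017	S018
met0001	0.2748976727900709	0.7243839676163717	1.7903055106813606	0.6520236685774864	2.694979791068489	10.87603434257122	0.7852693835593283	1.6919356856807743	1.1816901064085188	1.2901477743601995	1.397115485206437	4.497280341259502	15.55467781138277	1.3788205979674697	2.4813409451915	4.140362253975411	1.0221698815216078	10.194255660235427
met0002	0.6965501354013279	0.25265705843679354	1.6340774286475221	0.7452264981571611	3.912449348919871	1.9889798618656236	0.7379229212200099	0.042002125267426006	0.37182836328128643	0.907037667306094	0.21771902601656662	2.5454323476320595	0.12243804589727042	0.23914753011106776	0.8464353556753839	1.6296208317202552	0.6953288167876374	0.15013714100324954
met0003	0.628362386534548	0.5973522578094559	8.170558035654427	0.6847530227833599	0.7081829780394974	1.7429455611313163	3.3722755683407923	2.4615962570260717	1.3439752758847023	1.9430106091089736	1.0018846689383565	2.174722417286207	4.941341023987762	1.0911054731804009	2.6523294198512932	10.021315624797355	2.0351158158970986	0.2616014073698091
met0004	0.4998631788813876	1.1028971482276804	0.6063571299655723	0.7818222311265371	1.7592777395124053	8.50447955849854	2.6708344341089503	5.2051985535000185	0.8441845240888468	1.3841727429139474	1.0533844642729548	3.2495826127754754	11.360899375911517	1.265742987822111	7.2328609635031444	3.4281418137926503	3.0071426552867773	28.749484841245486
met0005	1.0046130887608966	0.04328875529296112	1.1065929060496824	0.5443894464701623	2.940314460275398	1.9728133522756977	0.2990113226046687	0.03783704568690149	0.8416600289468463	0.8252488680406408	0.22913386512263678	0.26458453407345073	0.050613913413462934	0.17691317942744572	0.9526974207550746	2.5714317454431823	0.39896713750816376	0.1905707761940525
met0006	4.91844417788416	0.3197141981107191	6.964276659586207	0.19779654865554025	2.7727927821953853	0.48480020562725445	2.2992634419337272	1.3779837794266958	0.9602826434057368	2.945987634062617	0.33995934267265654	1.8059808534649102	4.619614137728904	1.1123566973869794	2.2696563677033836	5.128672817832055	1.0034138429862565	0.3587271313499784
met0007	0.32011258184266733	0.8628561748875083	1.596784540209987	0.23890309378096872	2.741811323601284	6.3380782257707855	11.257493315883957	2.9494465540452137	2.2022505699762913	0.46904777298897465	1.5558877792462544	6.552633736869784	19.331272050606714	0.7784370461115752	4.299275154313301	6.1165990506520975	5.113330740447248	26.293510624913196
met0008	0.9007722088080072	0.19492140913720607	0.43359666240091693	0.6112534802402781	1.323181246072923	2.5194198695364847	0.4288020753804766	0.14596228630702618	0.17782542046576824	0.3943608908597025	0.20988827986193961	1.3732792957673876	0.13555914275296235	0.0732395755948928	0.4372578720940291	4.1567180036206794	0.36271579356436173	0.07746435851630494
met0009	0.9039023782310195	0.3116327127630664	2.641833260072779	0.20479737723901503	5.347606732004569	0.8832111085418145	2.278265148072523	3.3020501806831626	3.7382187172311565	1.0665111160297436	0.432223920273556	3.233652826449826	7.7937456760532955	3.2609718162173342	2.3248858739833573	10.459136462115891	1.401810508284624	0.2705478758377645
met0010	0.41351792160304046	0.45184327469393387	1.300936488911943	0.9903779330086507	2.3738228076839403	3.497639407439627	1.100058177955379	1.1342213003744326	1.2383470287003524	3.52051797582087	0.5857883153652116	0.8691571323049319	13.388739949410509	1.7793004842290545	3.7268789968268092	9.15360231699419	0.6445793452241618	4.921706230188617
met0011	1.1257971480148168	0.08111619693949085	1.856944335755828	1.1766485926926231	2.2927992580571566	2.7935228614918493	1.0387945669445042	0.15567066235383414	0.3262607173364346	0.6607480786074308	0.26841758301690116	0.2556004961838781	0.1508710206795131	0.05338521526771864	0.17146311724692756	3.2405409302815027	0.21832107886465682	0.05365206429345297
met0012	0.5327647122512132	0.5837266027227276	3.417987437493219	0.4787076733866937	2.4224150803476103	0.8071243685378053	2.2551421774255953	0.6165975240844788	3.0342696701480345	0.7376237561043401	0.6529035975158782	0.7385990819722014	6.2811265592506595	1.0532099607785026	4.09626574743705	6.277987777829145	1.4752451590027145	0.16257784260047167
met0013	0.4478948990024406	0.30471558297114926	1.776910191400117	0.48426325425578803	1.2072276258094659	4.275442991003976	1.6696233616859646	1.479360670680318	1.7469281288300929	2.322953037530505	0.7298851136744577	6.61684438919673	7.668833956555987	1.0796119424146693	4.346088113282411	5.314398218962802	1.0472711866816866	10.354250634067268
met0014	2.518131128694014	0.10708145161646279	0.9592366673954479	6.0382274419965025	13.634602478295669	3.2178562603425953	0.27708570740856137	0.10505234539549521	0.22955545710193473	0.8962702092766095	0.14622305978945432	0.2521758295844305	0.09454342297360394	0.04797297158428834	0.48389227813051555	5.5460112878059045	0.8509037861371227	0.23230197537549702
met0015	0.8164140977123763	0.23531421255723833	6.541566150119647	1.017314755337343	3.5300729639981108	2.17673557732736	4.409470085536827	2.1452039219996717	3.8214935149944798	5.465250919963502	1.3703214212384023	2.3185510061019765	25.126786401400945	3.2077624254733634	1.1874630508512092	11.710053287338178	2.5201567697886547	0.38281364872807444
met0016	0.5108953274606158	0.9445497687235501	1.091082295786838	0.5106987384073483	0.9635683635303175	18.880064033388336	2.6932579391627898	1.819871640223512	0.474627626528331	1.0724757756333287	1.337045453516276	1.827837959067851	11.01024763080944	0.9197780030787572	6.516940506418771	13.897016918548646	3.4465084714711005	19.22675358707964
met0017	1.0972871380228064	0.08966425944995912	0.765778717348605	0.7678394239941865	1.99233279875695	1.0320283283398417	0.1984262372443647	0.10986496660033604	0.694741550609114	0.9531434178297002	0.11369620738049967	0.681863831703766	0.0923959506003568	0.1445698708104043	0.6500653936252014	2.6572906757853105	0.28094351138124046	0.05234654444981652
met0018	1.2882113411507377	0.27178905160627487	3.0277537146746485	0.18188362689823726	1.6986691287009277	1.9193982340437559	1.6672503061801711	1.2217353009644976	2.911794304039366	2.238713928817797	2.933449635122587	0.919642655754339	3.9615966754658127	8.809077860291348	1.8837855385530407	2.1464915214119857	1.6579969172267794	0.0788275841448482
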