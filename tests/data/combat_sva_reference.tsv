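block	gene	s0	s1	s2	s3	s4	s5	s6
input	g0	1.8296	1.3140	1.9565	0.1649	0.7762	0.7591	1.9419
input	g1	1.8742	1.4101	0.2350	1.0284	1.3703	0.8715	1.2377
input	g2	0.5723	0.9155	0.9500	0.7804	0.0079	0.0749	0.6669
input	g3	1.6609	1.4382	1.1207	1.8115	1.6658	1.9471	0.6935
input	g4	1.2835	1.8693	1.8081	0.8939	0.0147	0.8635	0.7970
input	g5	1.0382	0.5109	0.2774	1.6720	0.4153	1.9152	1.5694
input	g6	1.4732	0.9246	1.9778	1.4752	1.8132	1.7755	0.0779
input	g7	0.2693	1.8800	1.8933	1.6221	1.2236	1.2800	1.4976
mean_only	g0	1.677520449990	1.161920449990	1.804420449990	0.012820449990	0.964218495685	0.947118495685	2.129918495685
mean_only	g1	1.773872312720	1.309772312720	0.134672312720	0.928072312720	1.484887006247	0.986087006247	1.352287006247
mean_only	g2	0.478148130671	0.821348130671	0.855848130671	0.686248130671	0.158437797268	0.225437797268	0.817437797268
mean_only	g3	1.568157754069	1.345457754069	1.027957754069	1.718757754069	1.778704998775	2.060004998775	0.806404998775
mean_only	g4	1.123722554955	1.709522554955	1.648322554955	0.734122554955	0.267481957687	1.116281957687	1.049781957687
mean_only	g5	0.947690522593	0.420390522593	0.186890522593	1.581490522593	0.488467938897	1.988367938897	1.642567938897
mean_only	g6	1.324064367626	0.775464367626	1.828664367626	1.326064367626	2.004024844540	1.966324844540	0.268724844540
mean_only	g7	0.151981470427	1.762681470427	1.775981470427	1.504781470427	1.365745737075	1.422145737075	1.639745737075
full	g0	1.654705307704	1.193702889859	1.768167694874	0.166282644813	0.978532502278	0.963691573388	1.990232549491
full	g1	1.704409898147	1.310203032502	0.312072267970	0.985986784675	1.422140095728	0.960135193675	1.299321631389
full	g2	0.432189396641	0.765325750213	0.798814107433	0.634187284689	0.280793835934	0.331296618631	0.777530161269
full	g3	1.590679975494	1.368165804963	1.050930739208	1.741154309046	1.700486280939	1.918989343902	0.945240891252
full	g4	1.057642616842	1.582100184106	1.527308782405	0.708839837384	0.461804260379	1.160389122761	1.105657862926
full	g5	1.036390092378	0.548399140161	0.332306048292	1.622941705340	0.539755568492	1.753414034716	1.473606649144
full	g6	1.341017963631	0.789512535425	1.848290364419	1.343028555786	1.850950780406	1.821739049460	0.506358825257
full	g7	0.366051102190	1.719706538725	1.730884049935	1.502963670976	1.336332763517	1.389756319077	1.595872732015
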