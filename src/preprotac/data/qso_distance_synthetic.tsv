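aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.000000	0.255362	0.567572	0.608468	0.609588	0.189849	0.526356	0.454786	0.652502	0.451373	0.453512	0.439517	0.235383	0.491649	0.748065	0.190829	0.240345	0.323801	0.870798	0.679043
C	0.255362	0.000000	0.658695	0.650550	0.395528	0.419252	0.493831	0.254960	0.661871	0.243095	0.244655	0.508288	0.297960	0.490387	0.709747	0.331674	0.263134	0.153711	0.677971	0.502284
D	0.567572	0.658695	0.000000	0.139648	0.822817	0.532696	0.390397	0.792604	0.277441	0.783442	0.679192	0.252406	0.428070	0.313208	0.382406	0.395316	0.429053	0.727079	0.929212	0.740648
E	0.608468	0.650550	0.139648	0.000000	0.752120	0.609079	0.325459	0.749136	0.151399	0.738390	0.622694	0.274043	0.457221	0.261580	0.247128	0.443429	0.431314	0.706312	0.830985	0.653027
F	0.609588	0.395528	0.822817	0.752120	0.000000	0.771717	0.507447	0.225292	0.708076	0.213165	0.177125	0.660287	0.586925	0.562618	0.695765	0.631891	0.492968	0.335223	0.332224	0.248153
G	0.189849	0.419252	0.532696	0.609079	0.771717	0.000000	0.579900	0.636057	0.675449	0.627901	0.609506	0.430195	0.255702	0.524768	0.783688	0.196247	0.323405	0.508980	1.000000	0.799240
H	0.526356	0.493831	0.390397	0.325459	0.507447	0.579900	0.000000	0.555230	0.320127	0.537913	0.407299	0.217019	0.365436	0.088530	0.340143	0.395328	0.291059	0.536457	0.561025	0.375563
I	0.454786	0.254960	0.792604	0.749136	0.225292	0.636057	0.555230	0.000000	0.721745	0.042380	0.180207	0.643967	0.509515	0.582735	0.753478	0.532742	0.421565	0.136825	0.552237	0.429812
K	0.652502	0.661871	0.277441	0.151399	0.708076	0.675449	0.320127	0.721745	0.000000	0.707846	0.593441	0.346583	0.505574	0.275585	0.165030	0.503879	0.457948	0.700246	0.762552	0.597014
L	0.451373	0.243095	0.783442	0.738390	0.213165	0.627901	0.537913	0.042380	0.707846	0.000000	0.156514	0.630206	0.492002	0.565346	0.737279	0.521799	0.406534	0.144253	0.533488	0.405556
M	0.453512	0.244655	0.679192	0.622694	0.177125	0.609506	0.407299	0.180207	0.593441	0.156514	0.000000	0.523857	0.420059	0.440735	0.603636	0.465360	0.332034	0.226187	0.448526	0.284870
N	0.439517	0.508288	0.252406	0.274043	0.660287	0.430195	0.217019	0.643967	0.346583	0.630206	0.523857	0.000000	0.273426	0.148842	0.427150	0.267811	0.253472	0.578968	0.766925	0.571441
P	0.235383	0.297960	0.428070	0.457221	0.586925	0.255702	0.365436	0.509515	0.505574	0.492002	0.420059	0.273426	0.000000	0.317369	0.578147	0.103498	0.130622	0.414031	0.777214	0.571402
Q	0.491649	0.490387	0.313208	0.261580	0.562618	0.524768	0.088530	0.582735	0.275585	0.565346	0.440735	0.148842	0.317369	0.000000	0.323752	0.340245	0.260989	0.547176	0.638567	0.446407
R	0.748065	0.709747	0.382406	0.247128	0.695765	0.783688	0.340143	0.753478	0.165030	0.737279	0.603636	0.427150	0.578147	0.323752	0.000000	0.599070	0.533579	0.752822	0.695278	0.551262
S	0.190829	0.331674	0.395316	0.443429	0.631891	0.196247	0.395328	0.532742	0.503879	0.521799	0.465360	0.267811	0.103498	0.340245	0.599070	0.000000	0.149998	0.425804	0.837401	0.632672
T	0.240345	0.263134	0.429053	0.431314	0.492968	0.323405	0.291059	0.421565	0.457948	0.406534	0.332034	0.253472	0.130622	0.260989	0.533579	0.149998	0.000000	0.339216	0.690386	0.486879
V	0.323801	0.153711	0.727079	0.706312	0.335223	0.508980	0.536457	0.136825	0.700246	0.144253	0.226187	0.578968	0.414031	0.547176	0.752822	0.425804	0.339216	0.000000	0.650365	0.498590
W	0.870798	0.677971	0.929212	0.830985	0.332224	1.000000	0.561025	0.552237	0.762552	0.533488	0.448526	0.766925	0.777214	0.638567	0.695278	0.837401	0.690386	0.650365	0.000000	0.207658
Y	0.679043	0.502284	0.740648	0.653027	0.248153	0.799240	0.375563	0.429812	0.597014	0.405556	0.284870	0.571441	0.571402	0.446407	0.551262	0.632672	0.486879	0.498590	0.207658	0.000000
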