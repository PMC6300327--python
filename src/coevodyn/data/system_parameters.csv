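parameter,definition,argentine_stem_weevil,lucerne_weevil,range_low,range_high
lambda,Intrinsic growth rate of the host,1-18,6-91,1,100
K,Host carrying capacity,720,773,50,800
eta,Intrinsic rate of attack of the parasitoid,42±22,33,20,64
c,Survival of parasitoid larvae,0.92,?,0.5,1
kappa,Spatial heterogeneity in parasitism,0.23-0.87,0.11,0.1,0.9
a,Searching efficiency,4.14,?,1,8
Gamma_n,Additive genetic variance in host,0.01,0.01,0,0.1
Gamma_p,Additive genetic variance in parasitoid,0,0.01,0,0.1
C_n,Cost to host character,1,1,0,2
C_p,Cost to parasitoid character,-,1,0,2
N0,Initial host density,K,K,50,800
P0,Initial parasitoid density,10,10,1,100
n0,Initial host character,1,1,0.5,1.5
p0,Initial parasitoid character,0.9,0.9,0.5,1.5
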