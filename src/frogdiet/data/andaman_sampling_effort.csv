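species,site,habitat,season,n
H_tigerinus,Karmatang,agriculture,dry,41
H_tigerinus,Karmatang,agriculture,wet,35
H_tigerinus,Karmatang,plantation,dry,29
H_tigerinus,Karmatang,plantation,wet,29
H_tigerinus,Webi,agriculture,dry,32
H_tigerinus,Webi,agriculture,wet,35
H_tigerinus,Webi,plantation,dry,48
H_tigerinus,Webi,plantation,wet,38
H_tigerinus,Wandoor,plantation,dry,38
H_tigerinus,Wandoor,plantation,wet,33
Limnonectes,Karmatang,agriculture,wet,17
Limnonectes,Karmatang,plantation,dry,5
Limnonectes,Karmatang,plantation,wet,26
Limnonectes,Karmatang,disturbed_forest,wet,25
Limnonectes,Karmatang,undisturbed_forest,wet,22
Limnonectes,Webi,agriculture,dry,14
Limnonectes,Webi,agriculture,wet,17
Limnonectes,Webi,plantation,dry,19
Limnonectes,Webi,plantation,wet,26
Limnonectes,Webi,disturbed_forest,dry,13
Limnonectes,Webi,disturbed_forest,wet,17
Limnonectes,Webi,undisturbed_forest,dry,13
Limnonectes,Webi,undisturbed_forest,wet,17
Limnonectes,Wandoor,agriculture,dry,7
Limnonectes,Wandoor,agriculture,wet,21
Limnonectes,Wandoor,plantation,dry,17
Limnonectes,Wandoor,plantation,wet,29
Limnonectes,Wandoor,disturbed_forest,dry,19
Limnonectes,Wandoor,disturbed_forest,wet,11
Limnonectes,Wandoor,undisturbed_forest,dry,30
Limnonectes,Wandoor,undisturbed_forest,wet,10
Fejervarya,Webi,agriculture,dry,1
Fejervarya,Webi,disturbed_forest,dry,1
Fejervarya,Wandoor,agriculture,dry,19
Fejervarya,Wandoor,agriculture,wet,17
Fejervarya,Wandoor,plantation,dry,13
Fejervarya,Wandoor,plantation,wet,2
Fejervarya,Wandoor,disturbed_forest,dry,10
Fejervarya,Wandoor,undisturbed_forest,dry,2
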