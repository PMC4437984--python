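species,flood_category,habitat_components
Alestes baremose,critical,most_threatened:1
Hydrocynus forskalli,moderate,least_threatened:0.5;threatened:0.5
Labeo horie,critical,threatened:1
Lates niloticus,low,least_threatened:1
Oreochromis niloticus,moderate,threatened:1
Synodontis schall,low,threatened:1
Tilapia zillii,low,most_threatened:1
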