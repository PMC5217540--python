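code,base_category,subgroup,kind,intensity_class
137..,,Tobacco consumption (parent),parent,
1371.,NEVER,Never smoked tobacco,status,
137l.,NEVER,Never smoked tobacco,status,
137F.,EX,Ex smoker (general),status,
137K.,EX,Ex smoker (general),status,
137S.,EX,Ex smoker (general),status,
137T.,EX,Ex smoker (general),status,
1377.,EX,Ex smoker intensity prior to quitting,intensity,trivial
1378.,EX,Ex smoker intensity prior to quitting,intensity,light
1379.,EX,Ex smoker intensity prior to quitting,intensity,medium
137a.,EX,Ex smoker intensity prior to quitting,intensity,heavy
137b.,EX,Ex smoker intensity prior to quitting,intensity,very_heavy
137A.,EX,Ex smoker type (non cigarette),status,
137B.,EX,Ex smoker type (non cigarette),status,
137j.,EX,Ex smoker (cigarette only),status,
137N.,EX,Ex smoker admin,cessation_admin,
du21.,SMOKER,Nicotine Replacement Therapy,therapy,
du22.,SMOKER,Nicotine Replacement Therapy,therapy,
du23.,SMOKER,Nicotine Replacement Therapy,therapy,
du31.,SMOKER,Therapy,therapy,
du41.,SMOKER,Therapy,therapy,
8H7i.,SMOKER,Passive cessation,cessation_admin,
8HTK.,SMOKER,Passive cessation,cessation_admin,
137R.,SMOKER,Smoker (general),status,
137P.,SMOKER,Smoker (general),status,
137C.,SMOKER,Smoker (general),status,
137m.,SMOKER,Smokers unwilling to quit,cessation_admin,
8I3M.,SMOKER,Smokers unwilling to quit,cessation_admin,
137L.,SMOKER,Active Cessation,cessation_admin,
8IEM.,SMOKER,Active Cessation,cessation_admin,
9OO1.,SMOKER,Administrative,cessation_admin,
9OO2.,SMOKER,Administrative,cessation_admin,
8CAL.,SMOKER,Advice,advice,
8CAg.,SMOKER,Advice,advice,
137V.,SMOKER,Smoking Value,status,
137X.,SMOKER,Smoking Value,status,
1372.,SMOKER,Smoking intensity,intensity,trivial
1373.,SMOKER,Smoking intensity,intensity,light
1374.,SMOKER,Smoking intensity,intensity,medium
1375.,SMOKER,Smoking intensity,intensity,heavy
1376.,SMOKER,Smoking intensity,intensity,very_heavy
137H.,SMOKER,Smoker type (non cigarette),status,
137J.,SMOKER,Smoker type (non cigarette),status,
137Q.,SMOKER,Smoker type (cigarette only),status,
E251.,SMOKER,Nicotine dependence,status,
U60A.,SMOKER,Toxicity,status,
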