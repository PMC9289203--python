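trait	n_cases	n_controls	n_total	ancestry
CEC			5293	European
CAD	60801	123504	184305	European
MI	43677	128199	171876	European
IS	40585	406111	446696	European
LAS	34217	406111	440328	European
SVS	5386	406111	411497	European
CES	7193	406111	413304	European
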