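group,mode,delivered_bin,est_le,est_gt
All,fully-automated,le,2,8
All,fully-automated,gt,0,8
All,semi-automated,le,9,1
All,semi-automated,gt,0,8
All,manual,le,9,1
All,manual,gt,0,8
X-irradiated,fully-automated,le,1,3
X-irradiated,fully-automated,gt,0,5
X-irradiated,semi-automated,le,3,1
X-irradiated,semi-automated,gt,0,5
X-irradiated,manual,le,3,1
X-irradiated,manual,gt,0,5
gamma-irradiated,fully-automated,le,2,4
gamma-irradiated,fully-automated,gt,0,3
gamma-irradiated,semi-automated,le,6,0
gamma-irradiated,semi-automated,gt,0,3
gamma-irradiated,manual,le,6,0
gamma-irradiated,manual,gt,0,3
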