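((Sp0001:2.363394692783152,(((((((Sp0002:0.24408276720501565,Sp0003:0.24408276720501565):0.35141249754099313,(Sp0004:0.22396331589837093,Sp0005:0.22396331589837093):0.37153194884763785):0.13859843886818002,(Sp0006:0.3673581694425172,Sp0007:0.3673581694425172):0.3667355341716716):0.03939740026654892,Sp0008:0.7734911038807377):0.0219676076894606,(Sp0009:0.14551023207296598,Sp0010:0.14551023207296598):0.6499484794972323):0.3026418201735295,((Sp0011:0.28685321635104977,Sp0012:0.28685321635104977):0.05060647338686586,Sp0013:0.3374596897379156):0.7606408420058122):0.7810739891373739,(Sp0014:0.08528340274156676,Sp0015:0.08528340274156676):1.793891118139535):0.48422017190205047):1.1923804999371277,(Sp0016:1.0840132703841663,((Sp0017:0.37378126503048836,(Sp0018:0.014002456011820819,Sp0019:0.014002456011820819):0.35977880901866754):0.037916973301074464,Sp0020:0.4116982383315628):0.6723150320526035):2.4717619223361136);
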