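study_id,tube_id,agent,concentration_mg_per_ml
AuGd_mix,1,gold,0
AuGd_mix,1,gadolinium,7.46
AuGd_mix,2,gold,0.98
AuGd_mix,2,gadolinium,6.67
AuGd_mix,3,gold,1.95
AuGd_mix,3,gadolinium,5.89
AuGd_mix,4,gold,3.25
AuGd_mix,4,gadolinium,5.1
AuGd_mix,5,gold,4.22
AuGd_mix,5,gadolinium,4.32
AuGd_mix,6,gold,5.2
AuGd_mix,6,gadolinium,3.53
AuGd_mix,7,gold,6.17
AuGd_mix,7,gadolinium,2.75
AuGd_mix,8,gold,7.15
AuGd_mix,8,gadolinium,2.36
AuGd_mix,9,gold,8.13
AuGd_mix,9,gadolinium,1.57
AuGd_mix,10,gold,9.43
AuGd_mix,10,gadolinium,0.79
AuGd_mix,11,gold,10.4
AuGd_mix,11,gadolinium,0
IGd_mix,1,iodine,8
IGd_mix,1,gadolinium,0
IGd_mix,2,iodine,7.2
IGd_mix,2,gadolinium,0.79
IGd_mix,3,iodine,6.4
IGd_mix,3,gadolinium,1.57
IGd_mix,4,iodine,5.6
IGd_mix,4,gadolinium,2.36
IGd_mix,5,iodine,4.8
IGd_mix,5,gadolinium,2.75
IGd_mix,6,iodine,4
IGd_mix,6,gadolinium,3.53
IGd_mix,7,iodine,3.2
IGd_mix,7,gadolinium,4.32
IGd_mix,8,iodine,2.4
IGd_mix,8,gadolinium,5.1
IGd_mix,9,iodine,1.6
IGd_mix,9,gadolinium,5.89
IGd_mix,10,iodine,0.8
IGd_mix,10,gadolinium,6.67
IGd_mix,11,iodine,0
IGd_mix,11,gadolinium,7.07
Au_only,1,gold,0
Au_only,2,gold,0.98
Au_only,3,gold,1.95
Au_only,4,gold,3.25
Au_only,5,gold,4.22
Au_only,6,gold,5.2
Au_only,7,gold,6.17
Au_only,8,gold,7.15
Au_only,9,gold,8.13
Au_only,10,gold,9.43
Au_only,11,gold,10.4
Gd_only,1,gadolinium,0
Gd_only,2,gadolinium,0.79
Gd_only,3,gadolinium,1.57
Gd_only,4,gadolinium,2.36
Gd_only,5,gadolinium,2.75
Gd_only,6,gadolinium,3.53
Gd_only,7,gadolinium,4.32
Gd_only,8,gadolinium,5.1
Gd_only,9,gadolinium,5.89
Gd_only,10,gadolinium,6.67
Gd_only,11,gadolinium,7.07
I_only,1,iodine,8
I_only,2,iodine,7.23
I_only,3,iodine,6.44
I_only,4,iodine,5.65
I_only,5,iodine,4.86
I_only,6,iodine,4
I_only,7,iodine,3.2
I_only,8,iodine,2.4
I_only,9,iodine,1.6
I_only,10,iodine,0.8
I_only,11,iodine,0
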