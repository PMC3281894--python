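species,model,rank,ibd_strength
BT,TREE_1_2,4,strong
BT,TREE_1_10,2,strong
BT,HAB_1_2,4,strong
BT,HAB_1_10,2,strong
BT,EO_5000,1,strong
BT,PANMIXIA,7,strong
BT,IBD,6,strong
EYR,TREE_1_2,4,strong
EYR,TREE_1_10,2,strong
EYR,HAB_1_2,4,strong
EYR,HAB_1_10,2,strong
EYR,EO_5000,1,strong
EYR,PANMIXIA,7,strong
EYR,IBD,6,strong
FH,TREE_1_2,1,none
FH,TREE_1_10,4,none
FH,HAB_1_2,1,none
FH,HAB_1_10,4,none
FH,EO_5000,6,none
FH,PANMIXIA,3,none
FH,IBD,7,none
GST,TREE_1_2,1,weak
GST,TREE_1_10,4,weak
GST,HAB_1_2,1,weak
GST,HAB_1_10,4,weak
GST,EO_5000,4,weak
GST,PANMIXIA,7,weak
GST,IBD,3,weak
SFW,TREE_1_2,4,strong
SFW,TREE_1_10,2,strong
SFW,HAB_1_2,4,strong
SFW,HAB_1_10,2,strong
SFW,EO_5000,1,strong
SFW,PANMIXIA,7,strong
SFW,IBD,6,strong
SPP,TREE_1_2,1,weak
SPP,TREE_1_10,4,weak
SPP,HAB_1_2,1,weak
SPP,HAB_1_10,4,weak
SPP,EO_5000,,weak
SPP,PANMIXIA,6,weak
SPP,IBD,3,weak
STP,TREE_1_2,3,weak
STP,TREE_1_10,3,weak
STP,HAB_1_2,,weak
STP,HAB_1_10,,weak
STP,EO_5000,,weak
STP,PANMIXIA,1,weak
STP,IBD,1,weak
WB,TREE_1_2,1,weak
WB,TREE_1_10,3,weak
WB,HAB_1_2,1,weak
WB,HAB_1_10,3,weak
WB,EO_5000,3,weak
WB,PANMIXIA,6,weak
WB,IBD,7,weak
WPH,TREE_1_2,3,weak
WPH,TREE_1_10,3,weak
WPH,HAB_1_2,3,weak
WPH,HAB_1_10,3,weak
WPH,EO_5000,3,weak
WPH,PANMIXIA,2,weak
WPH,IBD,1,weak
YTH,TREE_1_2,1,none
YTH,TREE_1_10,3,none
YTH,HAB_1_2,1,none
YTH,HAB_1_10,3,none
YTH,EO_5000,3,none
YTH,PANMIXIA,6,none
YTH,IBD,7,none
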