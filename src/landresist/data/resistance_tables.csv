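model,class,resistance
UNIFORM,all,1
TREE_1_2,tree,1
TREE_1_2,other,2
TREE_1_5,tree,1
TREE_1_5,other,5
TREE_1_10,tree,1
TREE_1_10,other,10
TREE_1_100,tree,1
TREE_1_100,other,100
HAB_1_2,habitat,1
HAB_1_2,other,2
HAB_1_10,habitat,1
HAB_1_10,other,10
BT_EO_100,native_tree,1
BT_EO_100,horticulture_pine,2000
BT_EO_100,unimproved_scattered,1.2
BT_EO_100,crop_improved_scattered,1.2
BT_EO_100,cleared_no_scattered,2000
BT_EO_100,urban,2000
BT_EO_5000,native_tree,3.07
BT_EO_5000,horticulture_pine,8000
BT_EO_5000,unimproved_scattered,4000
BT_EO_5000,crop_improved_scattered,6000
BT_EO_5000,cleared_no_scattered,8000
BT_EO_5000,urban,8000
EYR_EO_100,native_tree,1
EYR_EO_100,horticulture_pine,1.3
EYR_EO_100,unimproved_scattered,1.3
EYR_EO_100,crop_improved_scattered,1.3
EYR_EO_100,cleared_no_scattered,2000
EYR_EO_100,urban,2000
EYR_EO_5000,native_tree,2000
EYR_EO_5000,horticulture_pine,6010
EYR_EO_5000,unimproved_scattered,6010
EYR_EO_5000,crop_improved_scattered,8000
EYR_EO_5000,cleared_no_scattered,10000
EYR_EO_5000,urban,10000
FH_EO_100,native_tree,1
FH_EO_100,horticulture_pine,1.8
FH_EO_100,unimproved_scattered,1
FH_EO_100,crop_improved_scattered,1
FH_EO_100,cleared_no_scattered,1
FH_EO_100,urban,1.8
FH_EO_5000,native_tree,2.17
FH_EO_5000,horticulture_pine,2010
FH_EO_5000,unimproved_scattered,2010
FH_EO_5000,crop_improved_scattered,2010
FH_EO_5000,cleared_no_scattered,4010
FH_EO_5000,urban,4010
GST_EO_100,native_tree,1
GST_EO_100,horticulture_pine,1.3
GST_EO_100,unimproved_scattered,1.13
GST_EO_100,crop_improved_scattered,1.3
GST_EO_100,cleared_no_scattered,2000
GST_EO_100,urban,1.8
GST_EO_5000,native_tree,2.9
GST_EO_5000,horticulture_pine,2000
GST_EO_5000,unimproved_scattered,7.17
GST_EO_5000,crop_improved_scattered,2010
GST_EO_5000,cleared_no_scattered,6010
GST_EO_5000,urban,6010
SFW_EO_100,native_tree,1
SFW_EO_100,horticulture_pine,1.02
SFW_EO_100,unimproved_scattered,2000
SFW_EO_100,crop_improved_scattered,2000
SFW_EO_100,cleared_no_scattered,2000
SFW_EO_100,urban,1.8
SFW_EO_5000,native_tree,2000
SFW_EO_5000,horticulture_pine,6000
SFW_EO_5000,unimproved_scattered,10000
SFW_EO_5000,crop_improved_scattered,10000
SFW_EO_5000,cleared_no_scattered,10000
SFW_EO_5000,urban,10000
WB_EO_100,native_tree,1
WB_EO_100,horticulture_pine,1.8
WB_EO_100,unimproved_scattered,1.8
WB_EO_100,crop_improved_scattered,1.8
WB_EO_100,cleared_no_scattered,2000
WB_EO_100,urban,1.3
WB_EO_5000,native_tree,11.6
WB_EO_5000,horticulture_pine,6010
WB_EO_5000,unimproved_scattered,4000
WB_EO_5000,crop_improved_scattered,4000
WB_EO_5000,cleared_no_scattered,8000
WB_EO_5000,urban,8000
WPH_EO_100,native_tree,1
WPH_EO_100,horticulture_pine,1
WPH_EO_100,unimproved_scattered,1
WPH_EO_100,crop_improved_scattered,1
WPH_EO_100,cleared_no_scattered,1
WPH_EO_100,urban,1
WPH_EO_5000,native_tree,2.62
WPH_EO_5000,horticulture_pine,10.1
WPH_EO_5000,unimproved_scattered,5.6
WPH_EO_5000,crop_improved_scattered,6.32
WPH_EO_5000,cleared_no_scattered,2010
WPH_EO_5000,urban,7.45
YTH_EO_100,native_tree,1
YTH_EO_100,horticulture_pine,1.8
YTH_EO_100,unimproved_scattered,1
YTH_EO_100,crop_improved_scattered,1
YTH_EO_100,cleared_no_scattered,1
YTH_EO_100,urban,1.8
YTH_EO_5000,native_tree,2.17
YTH_EO_5000,horticulture_pine,2010
YTH_EO_5000,unimproved_scattered,2010
YTH_EO_5000,crop_improved_scattered,2010
YTH_EO_5000,cleared_no_scattered,6010
YTH_EO_5000,urban,6010
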