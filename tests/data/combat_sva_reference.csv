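"X0","X1","X2","X3","X4","X5"
2.26801643663192,2.25071336043476,2.11066444706509,2.22429889496083,2.17762506288704,2.19870448761164
2.40283154832316,2.33739049814957,2.38145840510923,2.32689760346829,2.33070956944688,2.37547980861465
2.00244578358683,2.12583016730456,2.10157303589319,2.08419298341808,2.09070472564956,2.32456850218547
2.12387436840585,2.32489971007215,2.02563276562963,2.18150593849523,2.21353721361337,2.27285894691003
2.51033082352799,2.52462704120581,2.39264476441243,2.38732081363424,2.54242636003817,2.40329604310154
1.97952082828556,1.99457068517884,2.00926814735599,2.18331356240494,2.10343522947289,2.18126236605148
2.14765553006059,2.21338208254411,2.2585233763732,2.16125564849906,2.229683779769,2.09474206126645
2.14550103042166,2.14536879697905,2.04744502418014,2.25173006348974,2.09175785796987,2.16868885518968
2.4734510691752,2.47446089811004,2.49280381799707,2.4203722051863,2.35182952873226,2.40433734098704
2.12543121898391,2.1508580403761,2.15526673475005,2.18943243513859,2.34160315292604,2.18133582946066
2.2940030241939,2.4794935704345,2.29136115305916,2.43575206268373,2.18755697341245,2.29768839800774
2.03195880102161,2.0989876725634,2.22219683076924,1.92294184793723,2.16272741965885,2.14368250592105
2.17222702033174,2.08078420003469,2.23972026314497,2.17682642526673,2.24385357737325,2.22323584853045
2.34205216675506,2.14759704852856,2.05323505905418,2.19973823234948,2.17312027533556,2.32125538651496
2.39731369890494,2.35029207658838,2.46681351582779,2.16803248257939,2.20027177272332,2.18134757422409
2.32760296157001,2.22255497613846,2.38467453198976,2.31019116593772,2.23446725329798,2.25541127822604
2.29328012451121,2.32072640008306,2.40741714619353,2.48604574453163,2.30489729280523,2.16077461867588
2.22027437321625,2.41643889811942,2.30544897044867,2.34205439909608,2.35928706036272,2.38047275236674
2.2794857079281,2.17929132439106,2.13567032456364,2.06035410807386,2.03818521125414,2.12404105092046
2.23751880068264,2.37990317728344,2.21957883563154,2.29471871258439,2.20081031946744,2.12082565742827
2.11842293262825,2.12206898806578,2.35842102751277,2.09975854342531,2.28220398457642,2.10811392417385
2.40801252578526,2.34025497534639,2.2768072751687,2.28807842433799,2.26922755265766,2.34584033481679
2.10090151327955,2.01458426389247,1.99417077239397,2.12305448882658,2.2849421403571,2.13833147017804
2.15404135443082,2.1711700266556,2.24553579924187,2.15025258527614,2.13108020894702,2.24424431498336
2.23710376779119,2.31572151069181,2.18054242661531,2.05856923698948,2.08004423106096,2.32595368872586
2.52638142499301,2.33799545542163,2.30443315127707,2.46668954462728,2.27647372329147,2.27565619330312
2.34889160051427,2.2380046727562,2.256763139424,2.24394808088484,2.32414056117886,2.39689097427371
2.42402283256876,2.47893912327475,2.24064723957621,2.41738637944577,2.34537407662554,2.31251414881138
2.30045228787471,2.35218843659869,2.47347328217858,2.26864097823825,2.38122256582871,2.34089152550627
2.1765484441303,2.30092533772608,2.26377955560058,2.32832728335673,2.19693070826647,2.15273134857071
2.16565336238504,2.21038269635967,2.21046499174337,2.09511460135161,2.197144985554,2.21323871969287
2.33963500486545,2.28763944493186,2.04302751353629,2.09168001346118,1.99924578067057,2.07055306586441
2.35175517377295,2.43765021972955,2.26713229522347,2.27113593018198,2.14886714133041,2.31376299288962
2.21290558139259,2.26276802471574,2.23890294716036,2.30561992880208,2.16632632242359,2.1860693714763
2.46805358810981,2.16008892912058,2.18605580082138,2.44266147314442,2.51455214525493,2.17993533594252
2.33486501835566,2.40292337710734,2.53564777948874,2.28687668390088,2.34748230554357,2.43923460586943
2.42678360216011,2.35635763443934,2.38618686306011,2.27241696488698,2.36711749771643,2.36764221613183
2.2950502115344,2.22561903763938,2.3264999170636,2.36819320901775,2.28853645473525,2.31035371755827
2.36056086072325,2.35904604059145,2.30062308184852,2.38907895699935,2.34756063888689,2.54157466518575
2.35223321697129,2.24836521117715,2.1499565066012,2.11737692890005,2.31081307221663,2.24030057797517
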