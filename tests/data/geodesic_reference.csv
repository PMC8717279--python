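lon1,lat1,lon2,lat2,dist_m
-56.4520879029,-16.8416823404,-56.0934899830,-16.6443143113,44035.8941257944
-57.8116453042,-16.0365664725,-57.5505056022,-15.7505021673,42238.9412798929
-57.7437727346,-16.8244210932,-57.8729747104,-16.3976561043,49199.0017779745
-56.7122697598,-16.2658575801,-56.7688555610,-16.5386188583,30783.7793242789
-56.8908304260,-17.4042741158,-56.5631992540,-17.2726097167,37750.5429486238
-56.4838245198,-16.9682110478,-56.0131264954,-16.5750899265,66415.6736118984
-56.4432330059,-17.2080419382,-56.4765120021,-17.6642381724,50612.7145639733
-57.6914210159,-16.4754265701,-57.4466588600,-16.0079168377,57975.8313437618
-57.3483492837,-16.9443104409,-57.3787934724,-17.2548390819,34518.7184952328
-57.7401569893,-16.7864426107,-58.0132476403,-16.6166286160,34662.3978073521
-57.1256961623,-16.2509827059,-56.9254310603,-16.4386160645,29816.4270590241
-56.3354803972,-16.2928534638,-56.4480020182,-16.5045253598,26327.9724366915
-56.6350089921,-17.2903712746,-56.9351007896,-17.7830090048,63150.4984120832
-56.4261512450,-16.5027237151,-56.2209858664,-16.2219946841,38020.7851701172
-57.0821684489,-16.6468882061,-57.4423714508,-17.0323581325,57389.0027947490
-56.6631940764,-16.7933556908,-56.5979579699,-16.5283568334,30140.6441156925
-56.7305633600,-16.6696308990,-56.6713561993,-16.8656808010,22595.8448500721
-57.9383643309,-16.8449239162,-58.2237796580,-16.9363952724,32050.8596628728
-56.2931938535,-17.1490907712,-56.7348911118,-17.3677068792,52834.8320265740
-57.4128124845,-16.5071252279,-57.3557803321,-16.2232270188,32002.3012677465
-56.6713729193,-16.8904197078,-56.3573525347,-17.2234467879,49757.7858717172
-57.9545758537,-17.3649282088,-57.7322165031,-17.4030509786,24003.0962238292
-57.6774564419,-16.7484328373,-58.0251443392,-16.5521124623,42986.2206095560
-57.1076874489,-16.9284681609,-57.3061753597,-16.7981855677,25598.1063946979
-57.2763747789,-17.3685251210,-57.6583688768,-16.9066274565,65309.1700166445
-56.1828386186,-16.4504392993,-56.4169686571,-15.9812629219,57639.1756386403
-56.4424981921,-16.4246647163,-56.4931366899,-16.6524231544,25777.8142864855
-57.8072180757,-16.1460964052,-57.8514417859,-16.4437330404,33274.3838536632
-57.3880867517,-16.6311706466,-57.7113139688,-16.2745563625,52429.6379073488
-56.4829609403,-16.4208055661,-56.5508679006,-16.2934967254,15846.7662168698
-56.8318040622,-16.5252300977,-57.2473597410,-16.6094226955,45319.1530632247
-57.9167716523,-16.7590137711,-58.0869104399,-17.1144895823,43313.8924828026
-57.7931940646,-16.6185331417,-58.1226010960,-16.1934130234,58747.4984503588
-56.8378777206,-16.9796952932,-56.7469622291,-17.4568914222,53690.0620391823
-56.0828815735,-16.7765448446,-55.8001463463,-17.1938148447,55127.8223411924
-57.0266833383,-16.7639395085,-56.5888568833,-16.6922114561,47358.9881030537
-57.0530211979,-17.0995365054,-57.2214522005,-17.0788641029,18072.4029335170
-57.1221770794,-17.4675818802,-56.7958851552,-17.0714211083,55911.1897935381
-57.7195018220,-16.6689457847,-58.1109260809,-16.4967056917,45915.5444447610
-57.4375324323,-16.5108660480,-57.2105378180,-16.2422185560,38365.3254152590
-57.7845181081,-16.1259822323,-58.0543041172,-16.5885696761,58748.3527253094
-56.8902950612,-16.9436165742,-56.5605053181,-16.6353651021,48986.9214849408
-57.3657222144,-16.0706509074,-57.5748043762,-16.0555937782,22433.9023321388
-57.4880698189,-16.0959346449,-57.8234620013,-16.5510240255,61812.2305900095
-57.1298058800,-16.0114366539,-56.7381286137,-15.7628286345,50162.8842105320
-56.2184150182,-16.1598300405,-56.1995566579,-16.3439009886,20469.0444330037
-56.4559751358,-16.5075081052,-56.5823174069,-16.9130414372,46857.8652965620
-56.5064207773,-17.1063092261,-56.0696076268,-17.3653386511,54588.9352410132
-57.7544841352,-16.2533309918,-58.1011998186,-16.5740626837,51295.3582717692
-56.8012344170,-16.1881569387,-57.1047997512,-16.3778332658,38643.2933407755
-56.4451903235,-16.0422603609,-56.4444491373,-16.3983628584,39406.7277841311
-57.9721274246,-17.1555159550,-58.3403052068,-16.9778572814,43847.1322872727
-57.7563349907,-16.7405051026,-57.5620725551,-16.6593884933,22579.9413723150
-57.6004486967,-16.2938132107,-57.3850415671,-16.0548292068,35072.0115744668
-57.7378844969,-17.3143692945,-57.3103219459,-17.4167911007,46832.6469038838
-57.3981026164,-16.7671239320,-57.2352384037,-16.3115006749,53334.0574185627
-57.4271075462,-16.1127873560,-57.9022480548,-16.0575893137,51200.4132284543
-56.7320497766,-17.3411538944,-57.0917101796,-17.4220395751,39254.7267032728
-56.0675361757,-16.6059361701,-55.6345129541,-16.3015752545,57208.3665239869
-57.0652367969,-16.3228548261,-57.5474000129,-16.7137108294,67233.4081604317
-56.3411427702,-16.3047743675,-56.6085020283,-16.2740047769,28777.2356743184
-56.7879683586,-16.1983915693,-56.6848612013,-16.2858200001,14666.3754999344
-57.2516319132,-16.8611768704,-57.0997008876,-16.4936862387,43778.6375297765
-57.0922062358,-17.1282406556,-57.3555438728,-16.8822263753,39084.0228744381
-56.3668624732,-17.3420828802,-56.8003036162,-17.2476492165,47252.8112610030
-57.7076535116,-16.2630037143,-57.8973188377,-16.6191317813,44310.9310989615
-56.1580590550,-17.2517024159,-56.3733389727,-17.5980890207,44640.4676829516
-57.7690198727,-17.4682779755,-58.2136244635,-17.7936365046,59353.9353730729
-57.8932361347,-16.6132842758,-57.7125216079,-16.7196538190,22587.1512920455
-57.3640178061,-16.7432106445,-56.9890128639,-16.3920790176,55783.3086550170
-57.9130498760,-17.2277523856,-58.1763050049,-17.4783648098,39397.5049859021
-56.8575346965,-16.8756063614,-57.3082805766,-17.0019922230,50009.3822349109
-56.9524941026,-17.3474921456,-56.6190355488,-17.7955302792,60925.8117936101
-56.1503162620,-17.3513302876,-55.8067413104,-16.9486771437,57638.0997163869
-56.0408586388,-16.2969611796,-55.7613810981,-16.1544779036,33784.8556893587
-56.4420072908,-17.2981716874,-56.4059392549,-17.2839488172,4145.2488203147
-56.2848557118,-16.8058009516,-56.3997662157,-16.6662376804,19715.2548704326
-57.4670733650,-17.2903473836,-57.4891960910,-17.3734580150,9493.9356158365
-57.5348601189,-16.9487322848,-57.6684676691,-17.1212367204,23807.7173604145
-57.2410718405,-16.4713849818,-57.4441953660,-16.0225270551,54210.0883301925
-56.1673039609,-16.7786343575,-56.3389427559,-16.7431995677,18715.5539973924
-56.3028790225,-16.5211189892,-55.9984871945,-16.4883967131,32698.4693693133
-56.7341647415,-17.0677665787,-56.4992715792,-17.3653619856,41339.2206109492
-56.6104037424,-16.2089213975,-56.9783009051,-16.0945416570,41333.4578855616
-57.8098085035,-16.4114265576,-58.2253152847,-15.9754867349,65584.1973677085
-57.7251841399,-16.0616796311,-57.4242999638,-15.9679976267,33830.0858598764
-56.4347517907,-16.3073277415,-55.9887247279,-16.5539443877,54900.4872742869
-56.8198482093,-17.3574262037,-56.7036825093,-17.6861348996,38414.1961344496
-56.8700987771,-16.6413542289,-56.9041136241,-16.6187224534,4409.4635559434
-56.4721532200,-16.3011329252,-56.4800000044,-16.2015394837,11053.0139121560
-56.1375275286,-17.3203996172,-56.5204239627,-17.7326906053,61115.8514467210
-56.6842734299,-16.8720875488,-56.4099520138,-16.7008561355,34846.9954060070
-57.3327244833,-16.1524501790,-57.0701923363,-16.3819152380,37845.6571095159
-57.2716159645,-17.0283400297,-57.6140043158,-17.3805566572,53346.5931328754
-56.1277450732,-16.8431439442,-56.2444252505,-16.6134582355,28300.4525928686
-56.8940138695,-16.0957900197,-56.6137123756,-16.1164204556,30072.7914666504
-57.2472810530,-16.0200526826,-57.0295208170,-15.5688580226,55110.1396371823
-57.7630428456,-16.2241994812,-57.6259689616,-16.6022778029,44327.0292204753
-56.8234840001,-16.4708554523,-57.3111813142,-16.5165374905,52315.0922196855
-56.3492009776,-17.0569614620,-56.3906528958,-17.1146473349,7760.3356096168
0.0000000000,0.0000000000,0.0000000000,1.0000000000,110574.3885577988
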