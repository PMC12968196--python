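0.0000000000 0.0111401117 -0.3646407239 -0.6494759403 -0.7299707538 -0.2585816395 0.2775654249 -0.4454015426 -0.4175250641 -0.0187181560 -0.9724815456 -0.8513278306 -0.5438928256 -0.2016257715 -0.6653453144 -0.6888931845 -0.8715026321 -0.0603615589 -0.8222081140 -0.1971313290 0.5956154461 0.3789880138 -0.8312877399 0.1409609768 -0.1589075740 -0.2723473617 0.8946047137 -0.1422447826 -0.7823966781 -0.3910969913 -0.2141012429 -0.0287038849 0.8754421228 -0.6960739886 -0.9801223233 0.7992450427 -0.5054407237 -0.1184323146 0.4911144860 -0.1203747292 -0.7164911431 -0.0563752988 -0.8638315424 -0.7208489407 0.4924311941 0.3256560416 0.9825242953 -0.2552915217 -0.4513051876 -0.4004714676 -0.4469035781 -0.6528359196 -0.1378621044 -0.6064269813 -0.6480344597 0.8755757656 -0.2386711217 -0.1641193442 0.4490075191 -0.6695182297 -0.9361386821 -0.4528139382 -0.9464160002 0.6279943114 -0.4142458910
0.0000000000 0.5100105011 -0.3488521636 0.7132406141 0.3771726410 -0.8024754247 -0.8505919490 -0.5964193657 -0.9074227592 -0.3394680018 -0.0872248477 -0.2946135918 0.5925300920 0.7251847817 0.6324548150 0.0810972445 0.4216897211 0.7744181998 -0.1522856040 0.9706416449 0.7569073582 -0.8292271227 -0.5077744348 0.7271064542 0.2492682633 0.2184312611 -0.1429039089 0.9727492107 0.4734430753 -0.8790048448 0.5428963112 0.8914053204 -0.0205856130 -0.0560413979 -0.0857626721 0.5887171085 0.3502380615 -0.0580130046 -0.8400023292 -0.9926614486 0.6946024583 -0.9420641516 -0.3737835849 0.2809926826 -0.2466855501 -0.4933560742 -0.1770920298 -0.3180171914 -0.0510355881 -0.5288023644 0.8902378469 -0.3635649757 -0.5923428168 -0.2825282505 -0.7531956822 -0.4767135871 -0.9211719792 -0.0707596996 -0.6392400125 -0.5271635432 0.2279233941 -0.0448854649 -0.3229488509 0.6492680825 -0.7502029357
0.0000000000 -0.8600960334 -0.8633303600 -0.2635694015 0.5699855239 -0.5377441106 -0.4465991168 -0.6677584939 0.0475053354 -0.9404313406 0.2160358059 -0.4341010900 -0.5942126592 -0.6583722964 0.3966314658 0.7203120277 0.2503216760 0.6297880072 0.5484367894 0.1378188532 -0.2689488641 0.4107924833 -0.2261101874 -0.6718974678 -0.9553081785 0.9370777442 -0.4233921104 -0.1830994124 -0.4046073313 -0.2727519498 0.8120494154 -0.4522970725 0.4828843776 -0.7157795499 -0.1788994002 -0.1209112399 0.7885828905 0.9912659977 -0.2306569934 -0.0115400604 0.0645590177 -0.3306613978 0.3377586386 -0.6335770806 0.8346602653 0.8065655129 -0.0573098786 0.9130669773 -0.8909090843 0.7483252388 -0.0880554812 -0.6645492988 -0.7938035195 0.7432523825 -0.1129052852 0.0781743853 0.3073731941 -0.9838993372 -0.6243111838 0.5233010022 -0.2677597696 0.8904744985 0.0008911966 0.4290385786 0.5153599684
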