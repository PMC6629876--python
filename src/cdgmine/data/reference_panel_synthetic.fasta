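>PleD GGDEF synthetic stand-in reference (random background, canonical residues at published positions)
KHRVVRGLAVCMCYTSTKFPGVVPNGRGEMMSCSARKKSYNQAMRPFGWHEWAKPFRFHG
DNYATTGEQGKHRETQDTWPFYHHPFFRWFWVLHVTSVPDPDVFRFGCQHIAAYCRCGLA
NCCHGPEADGFVRTGKQISSECIFVYEWHPECNLIDSHMAMHCTDHCEPNNNMQGIYTIV
MCTRQTSFWENRPHFQIEWYKLMFLRSRKNDSWFKQLKPPDSHEEVYWVEEYVSCGQYDH
QQIWVGKACPHYVMMAWQGMPWKLAGYSLSTIIWNMIPWCQDYCYAKEYGRNIGYMTPPS
GSNWNEEQTKMWWWEMNYFSVFDHQRDFIHEKSKNLVWKKKRTDDLSCCKPTTLLALAVG
KKETENLFRDFKHLLPCWARQFFWYKQVDSENLINHMCPLHVPEFPDNTNCYTCLNKPWD
EQNQDFNTIIYSTAPYLNTGEKQGMRLAIRRVGIHCNRHK
>TBD_1265 EAL synthetic stand-in reference (random background, canonical residues at published positions)
CVCDDDLMIDRWYPEERDYANEFNHSSGHQPIMLANGHLGCFTATFMCVPAYQYGIDQVS
RHKGWWTRSCETHCLSTANCARQDLANVYTFVITFEKPYKEYVWALTFYWPMQGRSCVQT
KVPENTPAVHHSNLQKGWDALIGKAMKKMQCFEYVYPQKNMRKELLTRTPKMPPGLLPNV
YGGQFWVQNPAPVEQIESFFEYARTFQIPDRYGMTALFGKCFSLYVRCMRSWELLAMWAA
NWSPDDGGGGSKVTTENQFATQYWMATIHQWTIVQNFVVDYCVDFGHTNICIRGHPHNIW
DDSTSVSCSTDPLCGLTHELNPQCYFMCRMCGKWYIADTTPLDQTMEWMNWDWYHSNTLK
GTACLRNCEFKYINPGFNVKLFTPHINFSSFPLWPCCFEWQWCIQGMVSGSTYYNYKPQV
CIWCEATPCNYACGDHRNIYQCAQCRDMGLLGTWQHANDMTWMAETNNCREMETAPIDNE
RQAIFMHFTRYGHVPFMFGNLGFVYHKEVCKREPGVFTIYELESRHRSIDMKMETMPWWF
EKKHWENWTAGVQATLRPLAECVRCSMLNYPNLFQQLHECEKVNGTCHRQSFLVPIVPHV
CILQTTCKNNNGKVAEWYRHMNIWITKQHNTMGMHIPPVAGVKAEDDMPYNYHEFLWLML
AFVQQHIGMEKWMQNCHPDSDTREGPVEWCIMSEYGHDIYCGEQPDHRKDMIHQMLKQWV
EWQAAADYFD
>Bd1817 HD-GYP synthetic stand-in reference (random background, canonical residues at published positions)
RYQWMDLHPWHTWILVCGSQVRYTDCSWQPMYYQCDPGFKSVWEMSPSLCLFDILIPEGF
MAWGKEKQMYERLAMCRGKISLSGASSIFKVRHKYEVFYYASTRKKPMDTACEVLRKENN
CWLTNDWLDQKHEVNETMNGWSCNDFSMITKITWHWVYQLMEHETACSVSSKNCMHHVYM
GRHDGEHTELNGRDSCIGSYWCKHNKAKGPDHGFGATMFLGCKQSTRDSKMPYTTNHEQR
PNPRYACWGMEGGPYVISRGRHCWNHNINVLMGFNYCWET
>PA4608 PilZ active synthetic stand-in reference
VDDDPTWPKQQALYKLFFFVNVQLMYTDYMRTKLRQFVAFPWNAGYKQDIDWSKKGMWWY
PLYIDVCTNTPCGCHEYQCTQYWDETKQIHKHCWIETIVN
>XC1028 PilZ inactive synthetic stand-in reference
LKEKGGQPCVYTNHNIGEHICYCKMTYDQVPINPFEPFPVDAEGLKHLGHEFKGIDYPEE
PGCGTTCQKQIEYFVVKMLENICMTGCILDYLWLMCDCFC
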