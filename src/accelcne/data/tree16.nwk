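(((homSap:0.065,panTro:0.07):0.09,((speTri:0.12,(jacJac:0.15,mesAur:0.16):0.04)rodAnc:0.10,(((eptFus:0.08,(myoLuc:0.05,myoDav:0.05):0.04)batAnc:0.10,((canFam:0.09,felCat:0.08):0.04,bosTau:0.12):0.03):0.02,(eriEur:0.22,sorAra:0.24):0.05):0.03):0.02):0.05,((echTel:0.18,eleEdw:0.16):0.05,loxAfr:0.08):0.06);
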