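(((((Sp0001:0.22671049262714002,Sp0002:1.2668450727005247):0.9282668009382409,((Sp0003:0.25960386403661967,Sp0004:0.6982216914318917):0.5377006556353932,((Sp0005:0.019439040758604597,Sp0006:0.01418581063918672):0.9972467915121345,Sp0007:0.6454882980468948):0.8618706374191121):0.03312860420975662):0.7780214131448524,(((Sp0008:0.003941489277354977,Sp0009:0.002596990523863419):0.2693449518635484,Sp0010:0.4000221515452289):0.05688849758243396,Sp0011:0.3078143859490718):2.547356629213916):0.07974840503714309,((Sp0012:1.3836455181012652,((Sp0013:1.8681942556263789,Sp0014:1.0426140803972428):0.02866945499615365,(Sp0015:0.3781100916269852,Sp0016:0.33994351898545894):0.7338790734408309):0.04685789552221361):0.427461118170637,(Sp0017:0.1522932573304677,Sp0018:0.5599322785520003):1.2566087746722487):0.7939979786228867):1.415114291839731,(((Sp0019:2.164215515726348,(Sp0020:0.9193926587057438,Sp0021:2.3480168320489714):0.5237195491505319):2.7192025928703187,(((Sp0022:2.7342938201634217,(((Sp0023:0.14998568088864084,Sp0024:0.1773360062550344):1.0587975548917758,Sp0025:0.7073919688330873):0.3564263092535755,(Sp0026:0.4420506960755742,Sp0027:0.2707847398062888):1.0271105701451542):0.039748339874193274):1.0937637730724752,(((Sp0028:0.12980803519069634,Sp0029:0.18873218752038656):0.3513053394574278,Sp0030:0.5678096730271494):0.7632227708801522,(((Sp0031:0.6273135787891841,Sp0032:0.7131677018935478):0.01193217696650857,Sp0033:0.30255898447161844):0.9231515073269511,((Sp0034:0.4383341240580503,(Sp0035:0.6602821010848794,(Sp0036:0.2694139996750576,((Sp0037:0.0052578239143659024,Sp0038:0.011644135235273037):0.1192186280529921,Sp0039:0.16233414414728203):0.0030183357721992694):0.09260102047101958):0.8907614068925678):0.06146001737101213,Sp0040:0.4603605220551833):0.3714362006050787):0.8179616996566433):0.35529381994878345):1.9735600661449155,(((Sp0041:0.016548309447496645,Sp0042:0.024160951186064823):0.6890043086870827,Sp0043:0.35019286491493945):0.8643950363165919,Sp0044:2.856982898502952):1.5804264333748066):0.04722530361505422):0.04144286025057231,(((((Sp0045:0.0008373949552586788,Sp0046:0.0014735263885998224):0.2231906000648833,Sp0047:0.27912100953375646):0.7066135510757983,Sp0048:0.6482807458287971):1.7878199650745827,Sp0049:2.5447230528787586):0.024633636121367975,Sp0050:2.4657635353384157):1.8474307969527133):0.09839843827943252);
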