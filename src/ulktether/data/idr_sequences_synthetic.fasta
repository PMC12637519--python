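>atg13_idr_230_363 SYNTHETIC composition-matched stand-in (not a database sequence)
EYLKAQPSDKKMKEPIPYEFKLSRQSERLEPPDGIECLAPSPAKMGSLPSSAGTSGGKNR
SLSGSADMKGYTDGAASGKQGEIHSQEACVKNKAQGTQSPNPSFEGPPRNIQEEKDADPS
AEEYQARVMAALEG
>ulk1_idr_277_831 SYNTHETIC composition-matched stand-in (not a database sequence)
IEQLTYSSATTTLRLAMPLEEGLELPTNGLRRGPKNNQYRKEDDKSGESVEPKAPMCDGS
GSGDPSEVAETNPDETTVATTRSGKSFMYLQFATKPELETAGPKLKLLPPRSPVPLPSRT
ANGPPTTPREMGNGTLRGLFATPSDTLGGQEQLIEKPVPSDASATSKKATEYPSFRSKED
QPDSLMQRGSESRPNASIGPPRAQTSDSRSEAIVMPPPEEEQPLASTARTAVDNPRDPEF
IGQAEPARLHDVKRDSVNDQLEIPMGAGTVYLQSEQEYYPAEPPQLKLSSSSGTNNLPSS
SLNYLFGIIAVDADGVSIENTEVSQLDHGDGKTRQSTKSGTTEMGPPARTRNLTSLQDPE
EIGNTLAEKNDYCVGVPFYIEEGLDKGHAKFSSEGGVSAGPATREMTATKENYDRTASDM
SLPYNEGGRLAIPSDRMKKQPNIPLPIEPKFELMVEGSVKEGDGPQSPIRPMVRPQVEET
SQREDNGGNAGKKELSEGRVSRSRAKPFDLGLGTGKFGPVPGTNKEIGAGEMQSGPWPRG
EASRPHRSRGESSGS
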