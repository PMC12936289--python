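id	mutant	wildtype
Flrt2	FSIVRTSLSHPPPD	FSIVRNSLSHPPPD
Cntnap4	RVRNTHSENALTGV	RVRNTHSENAHTGV
Lrrtm2	ISSPSYHVGDKEIP	ISSSSYHVGDKEIP
Fn1	SVVALHDDMENQPL	SVVALHDDMESQPL
Col8a1	GPPEIPGPKGEPGL	GPPGIPGPKGEPGL
Lamb2	HTMGDVRRAEELLQ	HTMGDVRRAEQLLQ
Fbln5	VMTRPIKGPRNIQL	VMTRPIKGPRDIQL
Plxna1	ELKPSSPLTLKGRN	ELKPSSPLILKGRN
Slc12a9	FLTHPAFSEPAEGT	FLTDPAFSEPAEGT
Flrt3	NQINNVGISSDLKN	NQINNVGIPSDLKN
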