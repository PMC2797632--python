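>synthetic_rprot_01 synthetic placeholder ribosomal protein
GLQLFNKFFLLLTPWLKFVYKDRQLSAKANQDLVPQIQSATTAEGEFGLRKTVLTLWEAHFKMSAPRRDL
KGPIDSVPGSVLANQLLINADGANSMGGTDGEWETLWFGNGTDGDHDDFSVAGVPLKSAVITVCS
>synthetic_rprot_02 synthetic placeholder ribosomal protein
NAYAEEESPIGFYEGGMSYVPLGASLLLLNIAQYLHLRVRDEILYIQALFNITRECAAQSAGFAVTNGLK
GANLFDLIYGIFVLQAEDTGLIDHPMVDIIEQIDDPECNEPDVFFFVSVKGRYDADNLILVLDSE
>synthetic_rprot_03 synthetic placeholder ribosomal protein
RLEADLAFPLVGLDYLQNLNVVVILLFKVDQAQPRQFPGGAAVMVLSDSVTMLLGVLAVFEPTKRDLAWN
TCKTQSYTKKSLLFRLGNDYDKSWVPIYAQKAIQLEANIICALLHKIVQLRG
>synthetic_rprot_04 synthetic placeholder ribosomal protein
KNKNLDYPANFDYPQYTKIADFLIGISQSSVLQGMHLILERKVSTNGMANRYAGSADSKEINCSPVLMVK
LQYVFTGGFLPIDLPDSKTTFLRMTQENDIHICNELGASSVELAVLYVQQDQTPFDIFAVVPALLSRNFF
QTVTKAPDLYEGFDVVKSDVLNNISHRNAPLYMQVENLNWFQTYLDSEQRAIRVIKAAND
>synthetic_rprot_05 synthetic placeholder ribosomal protein
AGLPVQTGNKRGVIIVVILTMITSRFSALEDLETFQLKFREEKSKKLDGMNTLDRANRGWGVLSLKTVLE
PMLLGPYYWATVMRKKTHRGKVNHSQFLTLMGRLQGQEGFIVYFHEMSKAKLTIRII
>synthetic_rprot_06 synthetic placeholder ribosomal protein
PSELSQGMRVMEKEQGDLIGRRLFYTAAVRVLKKKSRAVHAEGQPTVLQSGPGGVKGAELIMKTLKFFTV
MQINVMTWSRDNVSVIDEADLAHEQKDELESIGAEKMAKGKLMYCYSVSMRRKASSYLARLTLQRIAFEP
L
>synthetic_rprot_07 synthetic placeholder ribosomal protein
WKWGGKSALPLQTLIEKSQSSEKIAIWMLRAADGPAVAVHQVFESVTDVKKLGPPSSMYPGKVVGDIAMI
AIVIMPEDVLCLSYYVKEDIDAAKKKQGYKDKKNEETKFDDEGADDTDAMGIGGVFTASFNDSALFMKPW
KQFFFPPTTPLAQLINLITPSKVFGSGFVALAAMIAYLWNLQFTIVYTEKFAVISKLQPSWNP
>synthetic_rprot_08 synthetic placeholder ribosomal protein
VVKSIFGARLEIQVYLILFQRTAAPLSLPVIFPQAEAVASEILVSGISSVNSFVQKLTARAGLKFVPKRS
FLYTSSSAYCLQLPSHNQDTNCDSKCQGHRSSGTHENHMYIADKPPRDLNHQFVLQLADDGRVKEYGLLD
SW
>synthetic_rprot_09 synthetic placeholder ribosomal protein
KDGLDYAAANLLQVARTMLDYVGRYHAEVGAANETLVRDENDLGNAGFILLNIDFGGRHLFMLNKECVIG
SVRLPITATVVSNYRFVSDGANSTRTVLDDLVNYLVHQIKMVPIDDALAAGLTARLIQGVFGDCTDAWKM
RSQISDASTLDCDDRQLSQVKAIFIVGNVIKKAHRDTVWGV
>synthetic_rprot_10 synthetic placeholder ribosomal protein
PLYRLNAYQKKKPNASCRDEKERRGAASAGEMPRRSGRDAFGPVRVDIVMSSDKLTRKAATTKGRQKGRY
GVKTMGPPEELLRAVAKHSVVTTYVRHIVSLGYVHAVQGTENIIRATDRRALDSDDYSYSPNALLPAISR
KVGMGDDRLQERANSRGAVLDGVIVKIPLVMLLH
>synthetic_rprot_11 synthetic placeholder ribosomal protein
VGLFLIMRAYRGLGSAFFAQIIDGHNKSEYNIAFGLSDKLLGGIEASVAKTIYGSAAGQNRGQAKDYMHY
QPQNEFIARDDNDLRMGRRQGIQGSSLATVDMELGQEILAPPKKANSGNKRLSHWALTLFDNDVAMDKFN
ISDGDIAVVLDEHNARHEKLLDEIPPIYFTPANFLTENQLSHRDG
>synthetic_rprot_12 synthetic placeholder ribosomal protein
IATLVKTLPDDAVVKIVGAAQKEFCYGLRAQGFEENPKIILLYLLQFSAALPGSTQFFEAVSANLKVNGV
EDLLAVVDANNSFNTDIKRAVVCKYTEMVIDDSFHQKDLGDGGPKFLVDFIIENQGDVRLVGVSFNAEKP
SGHGDTNIPGGIEDKQAHFQLGEVVGRTMRDRESGPYEHKV
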