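"""Bundled seed alignments for the sub-family signature domains.

Short artificial domain alignments (six rows each, ~8%% pairwise
divergence from an internal consensus), one per signature domain of
the six chaperone sub-families plus the HSP90 auxiliary ATPase domain
and the four disaggregase domains. DOMAIN_CONSENSUS holds, per domain,
the column-wise best-scoring residue string of the PSSM built from the
alignment with default parameters (uniform background, pseudocount 1),
so an exact consensus copy attains the profile maximum score.
"""

DOMAIN_ALIGNMENTS: dict[str, list[str]] = {
    "pfam00011": [
        "WPIICELYHEHLHNKMLRCKWCPEPDMQMRKDAAKWNKKAGAVHTHPDVTPD",
        "WPIICPLYEEHHHNKMLRCKWCGGPSMQCRKDAAKWNKKAGFNLTHADVTMD",
        "WPIICPLYHEHHHNKMLRCKWDPEPSMQMRCDAAKWNKKAGFGLTHPDVTPD",
        "WPIICPLYHEHHHNKMLRCKWCTEPSMQMRKDAAKWNKKAGIGLTHPDVTPD",
        "WPIICPLYHDHHHCKKLRCIWCPEPSMQMRSDAAKWNKKAGFGLAHPDVTPD",
        "WLIICPLYHEHHHNKMKRCKWCPEPSMQMRKCIALWNKKAGFGLTHPDVTPD",
    ],
    "pfam00226": [
        "IWQRHLEFVDKPYCLFREFNWGTAWKFKSESQSFKQSPSCPNNTNDVD",
        "ICQRHLEFVDKPCYLFRMWNWGTAWCFKSESQSFKQILSVPWNTNFVD",
        "IWLRHLEFRDKPYCLFRMWLWGTAWCFKSESHSFKQIPSCPNNTNDVD",
        "IWQRHLMFVDKPYCLFRGWNWGTAWCVKSESQSFKQIPSCPNNTNDVD",
        "IWQWHGEFVDKPYCLFAMWNWGTAWCFKSESGQFKQIPSCPNHTNNVD",
        "IWQRHLEFVDKPYCLFRMWNWGTAWCFKSRSQSFKQIPSCPNKTNDVD",
    ],
    "pfam00118": [
        "KSCVVSGKIRWVRYVIDIDWALWWNIDDVHWNIRPMECTLMKMKGGSFFHIIDRVT",
        "KSCVQSAKIRWERYVIDIDWMLWWNIDDVHYNIRPMECHLMKMKGGSFFHIIDGVT",
        "KICVQSGKIRWERYVIDIDWALWWNIDDVHFNIRPMECHLQKMKGGSFFHIIDGVT",
        "KGCVQSGKLRWERYVIDIDWALWWNIDDVHWNIRMMECHLMKMKGGSVFHIIDGVT",
        "KSCVQCGKIRWSRYVIDIDWALWWNIDSKHWPIRPMEKHLMKMKGGSFFHLIDGLT",
        "KSRVQSGKIRWERYVINIDWALWWNMDDVHNNIRPMECHLMKMKGGSFFHIIDGVT",
    ],
    "pfam00012": [
        "WVWSRALNNTFSPDAHVAMWSCGKLRPQKRSDRSYPPYPKQFDDGQKCTCCHVHEMKC",
        "WVWSRALNNTFSPDAHVAMWSCGKLPPQKRSDRSYPPYPKQFDDGWKCTNCHVHEMKC",
        "WVWSRALNNTFSPDAHVAMWSCGDLPPQKRSDRSYPPYPKQGYDGWKCTVCHPHEMAC",
        "SVWSRALNNTFSPDAHVAMWSCGDLPPQKRSDRSYSPYPKQFDDGWKCTCCHVAEMKC",
        "WVNSRALNNTFSPDAHVAMSSCGKLPPQERSDRSYPPYPKQFDDGWKCTCCHVTEMGH",
        "WVWSRALNNTFSPDAHVAMWSCGKLPPQKRSDRSYPPYPKQFADGWKCTCCHVHEMKC",
    ],
    "pfam00183": [
        "EHFTFLQIVHHNNVGYVSHLNHLQLMRIKCNSETKFETGYWIATSLIQFEMTNA",
        "EHFLFLQPVKHNNVWYVSHLNHLTLMRIKCNSETKFETGYWIATSLIQFPMTNA",
        "EHFNMLQPVHHNNVWYVSHLNHLTLMRISCNSETKFETGYWIATSLIQFEMTNA",
        "EHFNFLQPVHHNNVWYVSHHNHLTLMRIKVNSETKFCTGYWIATSLIQFEMTNA",
        "EHFNFLQPVHLNNVWYVSVLNHLALMRIKCWSETKLETGYWIATSLIQFEFTNA",
        "EHFNFLQPVHFNNVWYVSHLNHLTLMRIKCNSETKFETGYWIATSLIQFEMTNA",
    ],
    "pfam02518": [
        "KLYMYRSLWCAATESGCWYFMCRRIDNSMRWKDQRKRKFSQLVCQAHFDH",
        "KLYMYRSLRCAATESGCWYFMCRRIDDSMRWKDQRKRKFSQLVCQAHPWH",
        "KLYMYRSLWCAATESGCWYFMCRRIDDSMRWKDQRKRKFSQLVCQAHPWH",
        "KLYMYRSLWCAATESQCWDFMCRRIDRSMKWKDQRKRMFSQLVCQAHPWH",
        "SLVYYRSLWCAATESGCWYFMCRRIDDSMRWKDQPKRKFSQLVCQAHPWH",
        "KLYMYRSLWCAATGSGCWYFMCRRIDDSMRWKDQRKRKKSQLVCQAHPWH",
    ],
    "pfam02861": [
        "QKAAVNEFVPSSCFSGTIHKSPATDTNQNRVVESNRPADYHPHAPM",
        "EKAAVNEFVISCCFHGTMHKSPHTDTNQNRVVESNRPADYHRHAPM",
        "EKAAVNLFVISTCFVGTIHKSPATDTNQNRVVDSTRPADYHRHAPK",
        "EKAAVNEFVISCCFSGTIHKSPATWTNHNRVVESNRPADYHRHAPM",
        "EKAAVNEFVISNCFSGTIHKSPATDTNQFRVVESNRPADYHRHAPM",
        "EKAAVNEFVIGCCFSGCIHKSPATDTFQNRVVESNRPADYHRHAPM",
    ],
    "pfam10431": [
        "GQCMYAIEICFCRQIFQWIIEPFHGCYWMAETDRPELDSLDNVD",
        "GQCMYAIEICFCRQIRQWIPEPFHGCYWWAETGRQEVDSLRNVD",
        "GQCMYAIHICFCRQIFQWIIEPFHGCYSMAETGRQEFDSLDNVD",
        "GQCMYAIEICWCRQIFFLIISPFAGCYWMAETGRQEVDSLPNVD",
        "GQCNYAIEICFCRQEFQWIIEPFHGCYWMAETGRCEVDSLDNVD",
        "GQCMYADEIWFCRPPFQWIIEPFHGCYWMAETGRQEVDSLDNVD",
    ],
    "pfam07724": [
        "QKFSHCYATPRFTKRDIKKEEPAMWTDFYPYKYAGFEEFNPERHFCGQMC",
        "QKFSHAYATPRYTKRDIKKEIPAKWTDFYPYKYEGFLEFEPERRFCGQMC",
        "QKFSHAYAGPRFTKRDIKKEIPPKWTDFYPYKYEGFEEFNPERHFCGQMC",
        "QKFSHAYATPRFTKRVIKKEIPAKWTDFYPRKYEGFEEGNPERHFCGQMC",
        "QKFSHSYATPRFTKRDIKKEIDAKWTDFYPYKYEGFEEFNHERHFCGQMC",
        "QKFSHAYAQPRLTKRDIKKEIPAKWTMFYPYKYEGFETFNPERHFCGQMH",
    ],
    "pfam07728": [
        "VEYSWTYAELRMMSRQVPSMFLFERITHMWLPTDTLMILLVMGDCTDI",
        "VEYSNTKYQLDMMCRQQPSMFLFERTTTMRLPTDTLMILLVMGDCTDI",
        "VTYSWTKAQLRMEMKQQPSMFLGERITTMRLPTDTYMILLVMGDCTDI",
        "VEYSWTFAQLRMMSRQQPSMFLFERITTMRLPTDWLMILLVMGDRTDI",
        "VELSWTAAQLRMMSRQQPSMFLFERITTGRLPTDTLCILLVMGDCTDI",
        "VEYSWTKAQLRMMSRQQPYMFLFERITTMRLPTDTGMILLVMGDCTDI",
    ],
}

DOMAIN_CONSENSUS: dict[str, str] = {
    "pfam00011": "WPIICPLYHEHHHNKMLRCKWCPEPSMQMRKDAAKWNKKAGFGLTHPDVTPD",
    "pfam00226": "IWQRHLEFVDKPYCLFRMWNWGTAWCFKSESQSFKQIPSCPNNTNDVD",
    "pfam00118": "KSCVQSGKIRWERYVIDIDWALWWNIDDVHWNIRPMECHLMKMKGGSFFHIIDGVT",
    "pfam00012": "WVWSRALNNTFSPDAHVAMWSCGKLPPQKRSDRSYPPYPKQFDDGWKCTCCHVHEMKC",
    "pfam00183": "EHFNFLQPVHHNNVWYVSHLNHLTLMRIKCNSETKFETGYWIATSLIQFEMTNA",
    "pfam02518": "KLYMYRSLWCAATESGCWYFMCRRIDDSMRWKDQRKRKFSQLVCQAHPWH",
    "pfam02861": "EKAAVNEFVISCCFSGTIHKSPATDTNQNRVVESNRPADYHRHAPM",
    "pfam10431": "GQCMYAIEICFCRQIFQWIIEPFHGCYWMAETGRQEVDSLDNVD",
    "pfam07724": "QKFSHAYATPRFTKRDIKKEIPAKWTDFYPYKYEGFEEFNPERHFCGQMC",
    "pfam07728": "VEYSWTKAQLRMMSRQQPSMFLFERITTMRLPTDTLMILLVMGDCTDI",
}

#: signature domains planted per sub-family by the synthetic generator
SUBFAMILY_DOMAINS: dict[str, list[str]] = {
    "SHSP": ["pfam00011"],
    "HSP40": ["pfam00226"],
    "HSP60": ["pfam00118"],
    "HSP70": ["pfam00012"],
    "HSP90": ["pfam00183", "pfam02518"],
    "HSP100": ["pfam02861", "pfam10431", "pfam07724"],
}
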