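# T-LGL leukemia survival-signaling Boolean network, 18-node reduced form:
# variant 4 - the connective inside the BID rule's negation is swapped from OR
# to AND, i.e. BID = NOT MCL1 OR NOT Apoptosis instead of NOT MCL1 AND NOT
# Apoptosis (the rule as printed contains a single connective, so the swap is
# applied to it).
CTLA4    = TCR AND NOT Apoptosis
TCR      = NOT (CTLA4 OR Apoptosis)
CREB     = IFNG AND NOT Apoptosis
IFNG     = NOT (SMAD OR P2 OR Apoptosis)
P2       = (IFNG OR P2) AND NOT Apoptosis
GPCR     = S1P AND NOT Apoptosis
SMAD     = GPCR AND NOT Apoptosis
Fas      = NOT (sFas OR Apoptosis)
sFas     = S1P AND NOT Apoptosis
Ceramide = Fas AND NOT (S1P OR Apoptosis)
DISC     = (Ceramide OR (Fas AND NOT FLIP)) AND NOT Apoptosis
Caspase  = ((BID AND NOT IAP) OR DISC) AND NOT Apoptosis
FLIP     = NOT (DISC OR Apoptosis)
BID      = NOT (MCL1 AND Apoptosis)
IAP      = NOT (BID OR Apoptosis)
MCL1     = NOT (DISC OR Apoptosis)
S1P      = NOT (Ceramide OR Apoptosis)
Apoptosis = Caspase OR Apoptosis
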