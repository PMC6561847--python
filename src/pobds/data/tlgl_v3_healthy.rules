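# T-LGL leukemia survival-signaling Boolean network, 18-node reduced form:
# variant 3 - the "NOT Apoptosis" factor is dropped from the IAP and P2 rules.
CTLA4    = TCR AND NOT Apoptosis
TCR      = NOT (CTLA4 OR Apoptosis)
CREB     = IFNG AND NOT Apoptosis
IFNG     = NOT (SMAD OR P2 OR Apoptosis)
P2       = IFNG OR P2
GPCR     = S1P AND NOT Apoptosis
SMAD     = GPCR AND NOT Apoptosis
Fas      = NOT (sFas OR Apoptosis)
sFas     = S1P AND NOT Apoptosis
Ceramide = Fas AND NOT (S1P OR Apoptosis)
DISC     = (Ceramide OR (Fas AND NOT FLIP)) AND NOT Apoptosis
Caspase  = ((BID AND NOT IAP) OR DISC) AND NOT Apoptosis
FLIP     = NOT (DISC OR Apoptosis)
BID      = NOT (MCL1 OR Apoptosis)
IAP      = NOT BID
MCL1     = NOT (DISC OR Apoptosis)
S1P      = NOT (Ceramide OR Apoptosis)
Apoptosis = Caspase OR Apoptosis
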