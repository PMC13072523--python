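# Synthetic reconstruction of the 13-factor influence matrix, encoded from the
# published qualitative descriptions of the factor interrelationships; the
# original prototype workbook's cell values are not publicly machine-readable.
# Row = influencing entity, column = influenced entity; cells in [-3, 3].
,D1,D2,D3,W1,W2,W3,W4,A1,A2,A3,TO1,TO2,TO3
D1,0,-2,3,3,3,3,2,3,2,1,2,2,2
D2,-3,0,-2,-1,-1,0,-1,-2,0,0,0,-1,0
D3,3,-2,0,3,2,1,2,2,1,1,1,2,1
W1,2,0,2,0,2,1,2,3,2,1,2,2,1
W2,1,0,1,2,0,1,2,2,1,1,1,1,1
W3,3,0,2,3,2,0,3,3,2,2,2,3,2
W4,2,0,2,1,1,1,0,2,1,1,1,1,1
A1,0,0,0,1,1,1,1,0,3,3,1,1,1
A2,0,0,0,2,2,2,3,2,0,1,1,2,2
A3,0,0,0,2,1,1,2,2,2,0,1,1,1
TO1,-1,0,-1,0,0,-1,-1,-1,0,0,0,3,3
TO2,-3,2,-3,-2,-1,-2,-2,-1,0,0,1,0,1
TO3,-1,0,-1,-1,0,-1,0,-2,0,-1,1,1,0
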