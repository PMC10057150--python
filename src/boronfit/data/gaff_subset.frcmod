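approximate GAFF/ff14SB-derived fallback subset for toy boronate fixtures (boronfit)
MASS

BOND
ca-ca     478.40     1.387
ca-ha     344.30     1.087
c2-ca     334.70     1.510
c2-ha     344.30     1.087
c3-h1     330.60     1.097
c3-hc     330.60     1.092
c3-n3     320.60     1.470
c3-ca     323.50     1.513
n3-hn     394.10     1.018
oh-ho     369.60     0.974
o -ho     369.60     0.974
o -c3     301.50     1.439
oh-2c     314.10     1.426
2c-h1     330.60     1.097
2c-cx     303.10     1.535
cx-hc     330.60     1.092

ANGLE
ca-ca-ca      66.60    120.00
ca-ca-ha      48.20    120.00
c2-ca-ca      64.60    120.00
c3-ca-ca      63.80    120.00
ha-c2-ha      37.80    109.50
h1-c3-h1      39.20    109.50
h1-c3-o       50.80    109.50
h1-c3-n3      49.40    109.50
h1-c3-ca      48.70    109.50
hc-c3-hc      39.40    109.50
hc-c3-n3      49.40    109.50
n3-c3-ca      66.20    109.50
c3-n3-hn      47.10    109.50
c3-n3-c3      52.30    109.50
hn-n3-hn      41.30    109.50
h1-2c-oh      50.80    109.50
h1-2c-h1      39.20    109.50
cx-2c-oh      67.70    109.50
cx-2c-h1      46.40    109.50
hc-cx-hc      39.40    109.50
2c-cx-hc      46.40    109.50

DIHE
X -ca-ca-X      4     14.5000    180.0000     2.000
X -c2-ca-X      4      0.7000    180.0000     2.000
X -c3-ca-X      6      0.0000      0.0000     2.000
X -c3-n3-X      6      1.8000      0.0000     3.000
X -c3-o -X      3      1.1500      0.0000     3.000
X -2c-oh-X      3      0.5000      0.0000     3.000
X -2c-cx-X      9      1.4000      0.0000     3.000
X -b -o -X      1      0.0000      0.0000     3.000
X -b -oh-X      1      0.0000      0.0000     3.000
X -b -c2-X      1      0.0000      0.0000     3.000
X -b -c3-X      1      0.0000      0.0000     3.000
X -b -ca-X      1      0.0000      0.0000     3.000

IMPROPER
X -X -ca-ha       1.1000    180.0000     2.000

NONBON
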