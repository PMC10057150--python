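built-in boronate covalent-warhead parameter library (boronfit, literal dialect)
MASS

BOND
b -o        450.00     1.510
oh-b        450.00     1.510
b -c2       340.00     1.630
b -ca       340.00     1.630
b -c3       326.80     1.510

ANGLE
ca-c2-ha        47.90    123.30
b -o -ho        35.00    109.50
ho-oh-b         35.00    109.50
b -c2-ha        50.00    109.50
b -c3-h1        50.00    109.50
b -c3-hc        50.00    109.50
b -c3-c3        50.00    109.50
b -c3-n3        50.00    109.31
b -c2-ca       127.38    120.97
b -ca-ca       127.38    120.97
b -o -c3        90.00    109.50
o -b -o         90.00    109.50
oh-b -o         90.00    109.50
oh-b -oh        90.00    109.50
oh-b -c2        60.00    109.50
oh-b -ca        60.00    109.50
oh-b -c3        60.00    109.50
o -b -c2        60.00    109.50
2c-oh-b         60.00    109.50
b -c3-ca       127.38    111.90

DIHE
oh-b -ca-ca      1     15.7206    170.3660    -1.001    ; nonstandard periodicity (literal dialect)
b -c2-ca-ca      1      0.7000    180.0000     2.000
b -o -c3-c3      1      3.4800    106.8800     1.500    ; nonstandard periodicity (literal dialect)
b -o -c3-h1      1      4.1053    256.5110     2.000
o -b -o -ho      1      0.8361      0.0000     3.000
o -b -c2-ha      1      2.5070    172.9780     0.129    ; nonstandard periodicity (literal dialect)
o -b -c2-ca      1     15.7206    170.3660    -1.000    ; nonstandard periodicity (literal dialect)
o -b -o -c3      1      0.8347      0.0000     3.000
ho-o -b -c2      1      2.0509    112.0440     5.000
c2-b -o -c3      1      2.3740    114.5990    -0.197    ; nonstandard periodicity (literal dialect)
cx-2c-oh-b       1      3.4800    106.8810     1.500    ; nonstandard periodicity (literal dialect)
ho-oh-b -o       1      0.8361      0.0000     3.000
ho-oh-b -c2      1      2.0509    112.0440     5.000
ho-oh-b -ca      1      2.0509    112.0440     5.000
oh-b -o -ho      1      0.8361      0.0000     3.000
oh-b -oh-ho      1      0.8361      0.0000     3.000
oh-b -c2-ha      1      2.5070    172.9780     0.129    ; nonstandard periodicity (literal dialect)
oh-b -c3-h1      1      2.5070    172.9780     0.129    ; nonstandard periodicity (literal dialect)
oh-b -c3-h1      1      0.5691      0.0000     2.385    ; nonstandard periodicity (literal dialect)
oh-b -c2-ca      1     15.7206    170.3660    -1.000    ; nonstandard periodicity (literal dialect)
oh-b -c3-ca      1     15.7205    170.3660     0.000    ; nonstandard periodicity (literal dialect)
h1-2c-oh-b       1      4.1053    256.5110     2.000
2c-oh-b -o       1      2.3743    114.5990    -0.197    ; nonstandard periodicity (literal dialect)
2c-oh-b -c2      1      2.3743    114.5990    -0.197    ; nonstandard periodicity (literal dialect)
oh-b -c3-n3      1     -2.2276      0.0000     2.156    ; nonstandard periodicity (literal dialect)
2c-oh-b -oh      1    -44.4201      0.0000     1.251    ; nonstandard periodicity (literal dialect)
2c-oh-b -c3      1    -12.2011      0.0000     2.000
ho-oh-b -c3      1      8.0608      0.0000    -0.101    ; nonstandard periodicity (literal dialect)
2c-oh-b -ca      1      2.3743    114.5990    -0.197    ; nonstandard periodicity (literal dialect)

IMPROPER
b -ha-c2-ha         1.1000    180.0000     2.000

NONBON
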