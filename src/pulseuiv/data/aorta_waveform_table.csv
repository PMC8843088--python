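# Fourier components of a cross-sectional mean velocity waveform measured in
# the abdominal aorta of a New Zealand White rabbit (after scaling by 0.7 and
# subtracting 0.1 m/s). Magnitudes only; the phases were not recorded and the
# fixture stores the coefficients as real and positive (zero phase).
# f1 = 3.3225 Hz (consistent with f8 = 26.58 Hz; the nominal period 0.3 s
# would give 3.333 Hz). alpha is the Womersley number of each harmonic for
# R = 2 mm and nu = 3.8785e-6 m^2/s.
n,f_hz,alpha,vj_ms
0,0.0,,0.100
1,3.3225,4.64,0.154
2,6.6450,6.56,0.094
3,9.9675,8.04,0.072
4,13.2900,9.28,0.029
5,16.6125,10.38,0.017
6,19.9350,11.37,0.010
7,23.2575,12.29,0.006
8,26.5800,13.13,0.003
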