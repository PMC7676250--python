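bracket,sex,gamma_kcal_per_kg,delta_kcal
0-3,male,59.5124283,-30.35372849
3-10,male,22.70554493,504.3021033
10-18,male,17.68642447,658.2217973
18-30,male,15.05736138,692.1606119
30-60,male,11.47227533,873.0879541
60+,male,11.71128107,587.7151052
0-3,female,58.31739962,-31.0707457
3-10,female,20.31548757,485.8986616
10-18,female,13.38432122,692.6386233
18-30,female,14.81835564,486.6156788
30-60,female,8.126195029,845.6022945
60+,female,9.082217973,658.4608031
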