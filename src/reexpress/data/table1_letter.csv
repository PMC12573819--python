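study_id,author_year,beta_observed,ci_observed_lower,ci_observed_upper,beta_rb,ci_rb_lower,ci_rb_upper,beta_dz,ci_dz_lower,ci_dz_upper,beta_alt,ci_alt_lower,ci_alt_upper,sigma_hat,n_obs,comments
abraham2020,Abraham 2020,-0.064,-0.11,-0.023,-0.032,-0.058,-0.0068,-0.037,-0.066,-0.0077,-0.038,-0.069,-0.008,0.78,101,
lee2020,Lee 2020,1.44,-0.37,3.26,1.31,0.16,2.47,3.30,0.53,6.34,3.46,0.56,6.66,0.83,124,
hamm2010,Hamm 2010,1.5,-7.6,10.6,3.7,-5.1,12.4,3.9,-5.4,13.3,3.9,-5.3,13.0,0.47,252,
apelberg2007,Apelberg 2007,-12.90,-27.80,2.00,-11.70,-25.10,1.77,-13.20,-28.60,1.92,-13.20,-28.60,1.92,0.62,293,
washino2009,Washino 2009,-10.94,-22.90,1.10,-11.40,-22.70,-0.04,-12.10,-24.10,-0.04,-10.00,-20.10,-0.03,0.53,428,
chen2012,Chen 2012,-11.3,-17.4,-5.2,-16.3,-26.0,-6.6,-17.9,-28.5,-7.2,-17.8,-28.4,-7.2,0.61,429,
pilkerton2018,Pilkerton 2018,-0.0049,-0.023,0.014,-0.021,-0.041,-0.00033,-0.03,-0.06,-0.00065,-0.031,-0.061,-0.00066,0.55,621,
stein2016,Stein 2016,-0.0039,-0.077,-0.0002,-0.0068,-0.013,-0.00013,-0.0069,-0.014,-0.000015,-0.0069,-0.014,-0.000015,0.52,1191,observed CI conspicuously asymmetric as printed; suspected typo left uncorrected
darrow2013,Darrow 2013,-2.30,-4.80,0.30,-1.95,-4.41,0.51,-2.02,-4.61,0.49,-2.00,-4.56,0.48,0.54,1630,
xu2020a,Xu 2020,0.51,0.16,0.81,0.51,0.26,0.76,0.96,0.49,1.44,1.01,0.51,1.50,0.81,1947,
xu2020b,Xu 2020,29.3,14.1,44.6,25.4,12.6,38.2,48.1,23.9,72.3,50.4,25.0,75.7,0.81,1947,second outcome from the same study
cheang2021,Cheang 2021,0.192,0.042,0.342,0.335,0.056,0.614,0.352,0.059,0.645,0.353,0.059,0.647,0.47,2899,
odebeatu2019,Odebeatu 2019,0.00069,0.00065,0.00073,0.011,0.0022,0.021,0.012,0.0023,0.022,0.012,0.0022,0.021,1.26,7765,
bulka1987,Bulka 1987,0.015,0.01,0.021,0.043,0.021,0.065,0.051,0.024,0.077,0.053,0.025,0.08,0.75,8778,year printed as 1987; suspected typo left uncorrected
steenland2018,Steenland 2018,0.0011,0.00093,0.0012,0.0012,0.001,0.0013,0.0013,0.0011,0.0014,0.0013,0.0011,0.0014,0.57,46294,
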