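# Published correlation matrix (lower triangle) of the 15 descriptors most
# sensitive in the powder classifier, as printed to 2 decimal places.
HSV Hue,1.00
R Median,0.67,1.00
R Std,-0.74,-0.68,1.00
G Mean,0.79,0.96,-0.81,1.00
G Std,-0.70,-0.60,0.97,-0.72,1.00
Y Mean,0.77,0.97,-0.80,1.00,-0.71,1.00
Y Std,-0.72,-0.61,0.99,-0.74,1.00,-0.73,1.00
Cb Max,-0.09,-0.31,0.21,-0.21,0.31,-0.21,0.27,1.00
Cb Std,-0.32,-0.58,0.47,-0.53,0.58,-0.54,0.54,0.72,1.00
Cb Mean,0.51,0.72,-0.57,0.80,-0.49,0.82,-0.51,0.06,-0.36,1.00
Cb Min,0.50,0.76,-0.64,0.83,-0.58,0.84,-0.59,-0.05,-0.48,0.97,1.00
Cr Mean,-0.82,-0.85,0.78,-0.95,0.70,-0.95,0.72,0.05,0.42,-0.89,-0.89,1.00
Cr Median,-0.81,-0.87,0.77,-0.96,0.71,-0.95,0.72,0.13,0.53,-0.88,-0.88,0.99,1.00
Cr Min,-0.28,-0.20,0.29,-0.31,0.12,-0.30,0.17,-0.75,-0.44,-0.39,-0.31,0.40,0.31,1.00
Saturation Mean,-0.67,-0.91,0.78,-0.96,0.69,-0.97,0.71,0.14,0.52,-0.92,-0.94,0.96,0.96,0.35,1.00
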