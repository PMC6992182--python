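fatty_acid,Sillago sihama,Odontamblyopus rubicundus,Harpadon nehereus,Lateolabrax japonicus,Selaroidea leptolepis,Cynoglossus lida,Branchiostegus albus,Nemipterus virgatus,Arius sinensis,Larimichthys polyactis,Trypauchen vagina,Siganus fuscessens,Mugil cephalus,Ilisha elongata,Collichthys lucidus,Leiognathus brevirostris,Coilia mystus,Johnius belangerii,Trichiurus lepturus,Pampus argenteus,Thryssa dussumieri,Thryssa kammalensis
C14:0,2.95,2.99,7.47,2.54,5.24,5.15,4.33,3.69,2.1,2.22,3.41,9.27,6.12,3.05,2.09,4.39,3.91,2.34,5.28,5.43,7.86,2.61
C15:0,0.60,1.50,0.40,0.76,0.97,1.25,0.71,1.29,0.55,0.70,0.87,1.61,0.62,0.5,0.41,0.81,0.44,0.78,0.49,1.16,0.7,0.62
C16:0,20.9,20.2,26.3,25.2,31.7,20.2,26.1,28.6,33.3,26.1,19.2,24.9,26.0,23.4,24.5,25.0,26.0,24.7,27.3,26.6,28.5,27.3
C17:0,1.72,2.04,0.78,1.85,1.59,3.07,0.99,2.03,1.26,1.17,2.41,1.26,0.63,0.82,0.77,1.20,0.94,1.38,0.78,1.88,0.62,1.06
C18:0,8.34,8.24,3.63,9.29,8.24,6.72,7.82,9.96,6.82,8.21,8.62,5.56,5.59,5.76,5.55,5.96,3.87,5.98,5.92,8.90,6.03,6.34
C14:1,0.50,0.43,0.44,0.37,0.31,0.40,0.56,0.26,0.20,0.32,0.28,0.59,0.08,0.27,0.20,0.49,0.25,0.28,0.47,0.32,0.29,0.25
C15:1,0.32,0.36,0.66,0.42,0.13,0.30,0.30,0.19,0.25,0.22,0.51,0.23,0.10,0.11,0.09,0.24,0.33,0.21,0.12,0.91,ND,0.09
C16:1n-7,14.4,10.8,19.9,8.10,10.7,9.32,8.88,6.06,8.06,9.05,8.93,11.7,11.8,7.06,11.1,11.2,10.3,15.5,8.68,6.91,10.2,6.79
C17:1,0.94,1.25,0.48,0.98,0.57,1.02,0.91,0.74,0.65,0.63,0.49,0.57,0.21,0.55,0.67,0.68,4.46,0.85,0.51,0.62,0.10,0.69
C18:1n-7,5.90,3.72,2.81,3.93,3.88,4.38,2.70,2.74,2.52,3.12,5.60,2.77,5.86,3.38,3.26,3.82,14.91,4.22,2.51,2.00,6.83,2.76
C18:1n-9,11.2,8.92,13.0,11.7,7.97,8.37,18.8,7.80,22.3,12.7,9.46,5.96,11.2,17.3,20.2,13.1,14.1,11.6,18.5,13.7,13.0,16.7
C20:1,0.88,1.31,0.97,0.91,0.28,3.96,1.40,0.77,1.02,0.76,0.79,0.73,0.29,0.82,0.97,1.49,1.06,1.88,0.53,1.93,0.46,0.52
C22:1,0.58,0.42,0.31,0.79,0.38,3.66,0.57,0.41,0.71,0.45,0.61,1.31,0.21,0.86,0.68,0.76,0.38,0.58,0.50,1.83,ND,0.54
C24:1,0.11,0.1,0.16,0.15,0.07,0.16,0.28,0.28,0.14,0.4,0.11,0.14,0.06,0.22,0.11,0.10,0.23,0.27,ND,0.83,0.12,0.45
C18:2n-6,1.20,1.16,0.57,1.63,1.05,1.09,0.68,1.2,1.02,0.77,2.81,1.89,6.21,1.04,0.84,1.19,0.93,1.06,0.6,0.84,1.01,0.83
C18:3n-3,0.88,0.55,0.45,0.96,0.62,0.64,0.17,0.38,1.00,0.35,1.02,1.18,1.81,0.95,0.8,1.31,1.03,0.85,0.74,0.3,0.46,0.49
C18:3n-6,0.10,0.12,0.08,0.11,0.18,0.18,0.06,0.1,0.07,0.09,0.32,0.23,0.53,0.11,0.11,0.17,0.09,0.11,0.13,0.04,0.13,0.09
C18:4n-3,1.84,1.70,0.09,0.84,0.53,ND,1.16,ND,0.78,0.12,1.96,1.06,ND,0.9,0.68,1.72,ND,0.27,ND,ND,ND,0.48
C20:2n-6,0.56,0.56,0.11,0.41,0.12,0.04,0.30,0.27,0.22,0.16,0.28,0.23,0.17,0.25,0.18,0.43,0.19,0.27,ND,0.21,0.2,0.17
C20:3n-3,2.07,5.38,1.43,2.72,1.82,1.67,1.95,2.57,1.67,2.39,2.25,1.57,0.15,1.24,1.02,1.28,1.03,2.65,0.76,1.98,0.13,2.33
C20:4n-6,0.12,0.06,0.03,0.06,ND,0.12,ND,ND,0.08,ND,0.05,ND,1.4,ND,0.12,0.11,0.03,0.05,ND,ND,1.33,ND
C20:5n-,8.94,4.32,5.73,5.10,5.74,8.33,2.04,4.73,4.76,4.40,8.09,2.97,8.23,8.11,7.17,6.76,3.73,6.55,2.44,3.09,9.1,5.58
C22:4,0.25,0.26,0.20,0.15,0.21,0.44,0.07,0.16,0.23,0.13,0.53,0.24,0.32,0.3,0.38,0.42,0.17,0.25,0.13,0.13,0.29,0.15
C22:5n-3,3.31,3.45,0.94,2.13,1.34,2.61,1.84,1.66,1.14,1.17,3.92,3.95,2,0.96,0.89,1.33,0.91,1.08,0.75,1.2,1.58,0.74
C22:5n-6,0.52,1.83,0.33,0.05,0.56,0.61,0.63,1.11,0.40,0.7,0.54,1.1,ND,0.31,0.25,0.62,0.42,0.69,0.2,1.01,ND,0.47
C22:6n-3,4.15,8.2,5.25,9.16,7.12,7.68,6.44,14.21,3.31,9.6,6.61,11.15,5.35,7.83,5.11,5.99,6.52,7.17,4.54,10.95,7.34,10.1
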