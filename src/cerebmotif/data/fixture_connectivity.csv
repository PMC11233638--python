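cell_id,III,IV_V,VI_VII,VIII,IX,X,amp_III,amp_IV_V,amp_VI_VII,amp_VIII,amp_IX,amp_X,amp_terminal
c01,1,1,1,1,1,1,60.0,80.0,100.0,120.0,140.0,160.0,340.8
c02,1,1,1,1,1,1,60.0,80.0,100.0,120.0,140.0,160.0,340.8
c03,1,1,1,1,1,1,60.0,80.0,100.0,120.0,140.0,160.0,340.8
c04,1,1,1,1,1,0,60.0,80.0,100.0,120.0,140.0,,340.8
c05,1,1,1,0,0,1,60.0,80.0,100.0,,,160.0,340.8
c06,0,0,1,1,1,1,,,100.0,120.0,140.0,160.0,340.8
c07,0,0,1,1,1,1,,,100.0,120.0,140.0,160.0,340.8
c08,0,0,1,1,1,0,,,100.0,120.0,140.0,,340.8
c09,0,0,1,1,1,0,,,100.0,120.0,140.0,,340.8
c10,0,0,1,1,1,0,,,100.0,120.0,140.0,,340.8
c11,0,0,1,1,1,0,,,100.0,120.0,140.0,,340.8
c12,0,0,1,0,0,1,,,100.0,,,160.0,340.8
c13,0,0,1,0,0,1,,,100.0,,,160.0,340.8
c14,1,1,1,0,0,0,60.0,80.0,100.0,,,,340.8
c15,1,1,1,0,0,0,60.0,80.0,100.0,,,,340.8
c16,0,0,0,1,1,1,,,,120.0,140.0,160.0,340.8
c17,1,1,0,0,0,1,60.0,80.0,,,,160.0,340.8
c18,1,1,0,0,0,0,60.0,80.0,,,,,340.8
c19,1,1,0,0,0,0,60.0,80.0,,,,,340.8
c20,1,1,0,0,0,0,60.0,80.0,,,,,340.8
c21,1,0,0,0,0,0,60.0,,,,,,340.8
c22,0,1,0,0,0,0,,80.0,,,,,340.8
c23,0,0,1,0,0,0,,,100.0,,,,340.8
c24,0,0,1,0,0,0,,,100.0,,,,340.8
c25,0,0,1,0,0,0,,,100.0,,,,340.8
c26,0,0,1,0,0,0,,,100.0,,,,340.8
c27,0,0,1,0,0,0,,,100.0,,,,340.8
c28,0,0,1,0,0,0,,,100.0,,,,340.8
c29,0,0,1,0,0,0,,,100.0,,,,340.8
c30,0,0,1,0,0,0,,,100.0,,,,340.8
c31,0,0,1,0,0,0,,,100.0,,,,340.8
c32,0,0,1,0,0,0,,,100.0,,,,340.8
c33,0,0,1,0,0,0,,,100.0,,,,340.8
c34,0,0,0,1,1,0,,,,120.0,140.0,,340.8
c35,0,0,0,1,1,0,,,,120.0,140.0,,340.8
c36,0,0,0,1,1,0,,,,120.0,140.0,,340.8
c37,0,0,0,1,0,0,,,,120.0,,,340.8
c38,0,0,0,0,1,0,,,,,140.0,,340.8
c39,0,0,0,0,0,1,,,,,,160.0,340.8
c40,0,0,0,0,0,1,,,,,,160.0,340.8
c41,0,0,0,0,0,1,,,,,,160.0,340.8
c42,0,0,0,0,0,0,,,,,,,340.8
c43,0,0,0,0,0,0,,,,,,,340.8
c44,0,0,0,0,0,0,,,,,,,340.8
c45,0,0,0,0,0,0,,,,,,,340.8
c46,0,0,0,0,0,0,,,,,,,340.8
c47,0,0,0,0,0,0,,,,,,,340.8
c48,0,0,0,0,0,0,,,,,,,340.8
c49,0,0,0,0,0,0,,,,,,,340.8
c50,0,0,0,0,0,0,,,,,,,340.8
c51,0,0,0,0,0,0,,,,,,,340.8
c52,0,0,0,0,0,0,,,,,,,340.8
c53,0,0,0,0,0,0,,,,,,,340.8
c54,0,0,0,0,0,0,,,,,,,340.8
c55,0,0,0,0,0,0,,,,,,,340.8
c56,0,0,0,0,0,0,,,,,,,340.8
c57,0,0,0,0,0,0,,,,,,,340.8
c58,0,0,0,0,0,0,,,,,,,340.8
c59,0,0,0,0,0,0,,,,,,,340.8
c60,0,0,0,0,0,0,,,,,,,340.8
c61,0,0,0,0,0,0,,,,,,,340.8
c62,0,0,0,0,0,0,,,,,,,340.8
c63,0,0,0,0,0,0,,,,,,,340.8
c64,0,0,0,0,0,0,,,,,,,340.8
c65,0,0,0,0,0,0,,,,,,,340.8
c66,0,0,0,0,0,0,,,,,,,340.8
c67,0,0,0,0,0,0,,,,,,,340.8
c68,0,0,0,0,0,0,,,,,,,340.8
c69,0,0,0,0,0,0,,,,,,,340.8
c70,0,0,0,0,0,0,,,,,,,340.8
c71,0,0,0,0,0,0,,,,,,,340.8
c72,0,0,0,0,0,0,,,,,,,340.8
c73,0,0,0,0,0,0,,,,,,,340.8
c74,0,0,0,0,0,0,,,,,,,340.8
c75,0,0,0,0,0,0,,,,,,,340.8
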