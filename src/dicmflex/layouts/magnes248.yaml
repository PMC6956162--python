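system: magnes248
channels:
  A1: frontal/L
  A2: frontal/L
  A3: frontal/L
  A4: frontal/L
  A5: frontal/L
  A6: frontal/L
  A7: frontal/L
  A8: frontal/L
  A9: frontal/L
  A10: frontal/L
  A11: frontal/L
  A12: frontal/L
  A13: frontal/L
  A14: frontal/L
  A15: frontal/L
  A16: frontal/L
  A17: frontal/L
  A18: frontal/L
  A19: frontal/L
  A20: frontal/L
  A21: frontal/L
  A22: frontal/L
  A23: frontal/L
  A24: frontal/L
  A25: frontal/L
  A26: frontal/L
  A27: frontal/L
  A28: frontal/L
  A29: frontal/L
  A30: frontal/L
  A31: frontal/R
  A32: frontal/R
  A33: frontal/R
  A34: frontal/R
  A35: frontal/R
  A36: frontal/R
  A37: frontal/R
  A38: frontal/R
  A39: frontal/R
  A40: frontal/R
  A41: frontal/R
  A42: frontal/R
  A43: frontal/R
  A44: frontal/R
  A45: frontal/R
  A46: frontal/R
  A47: frontal/R
  A48: frontal/R
  A49: frontal/R
  A50: frontal/R
  A51: frontal/R
  A52: frontal/R
  A53: frontal/R
  A54: frontal/R
  A55: frontal/R
  A56: frontal/R
  A57: frontal/R
  A58: frontal/R
  A59: frontal/R
  A60: frontal/R
  A61: temporal/L
  A62: temporal/L
  A63: temporal/L
  A64: temporal/L
  A65: temporal/L
  A66: temporal/L
  A67: temporal/L
  A68: temporal/L
  A69: temporal/L
  A70: temporal/L
  A71: temporal/L
  A72: temporal/L
  A73: temporal/L
  A74: temporal/L
  A75: temporal/L
  A76: temporal/L
  A77: temporal/L
  A78: temporal/L
  A79: temporal/L
  A80: temporal/L
  A81: temporal/L
  A82: temporal/L
  A83: temporal/L
  A84: temporal/L
  A85: temporal/L
  A86: temporal/L
  A87: temporal/R
  A88: temporal/R
  A89: temporal/R
  A90: temporal/R
  A91: temporal/R
  A92: temporal/R
  A93: temporal/R
  A94: temporal/R
  A95: temporal/R
  A96: temporal/R
  A97: temporal/R
  A98: temporal/R
  A99: temporal/R
  A100: temporal/R
  A101: temporal/R
  A102: temporal/R
  A103: temporal/R
  A104: temporal/R
  A105: temporal/R
  A106: temporal/R
  A107: temporal/R
  A108: temporal/R
  A109: temporal/R
  A110: temporal/R
  A111: temporal/R
  A112: temporal/R
  A113: parietal/L
  A114: parietal/L
  A115: parietal/L
  A116: parietal/L
  A117: parietal/L
  A118: parietal/L
  A119: parietal/L
  A120: parietal/L
  A121: parietal/L
  A122: parietal/L
  A123: parietal/L
  A124: parietal/L
  A125: parietal/L
  A126: parietal/L
  A127: parietal/L
  A128: parietal/L
  A129: parietal/L
  A130: parietal/L
  A131: parietal/L
  A132: parietal/L
  A133: parietal/L
  A134: parietal/L
  A135: parietal/L
  A136: parietal/L
  A137: parietal/R
  A138: parietal/R
  A139: parietal/R
  A140: parietal/R
  A141: parietal/R
  A142: parietal/R
  A143: parietal/R
  A144: parietal/R
  A145: parietal/R
  A146: parietal/R
  A147: parietal/R
  A148: parietal/R
  A149: parietal/R
  A150: parietal/R
  A151: parietal/R
  A152: parietal/R
  A153: parietal/R
  A154: parietal/R
  A155: parietal/R
  A156: parietal/R
  A157: parietal/R
  A158: parietal/R
  A159: parietal/R
  A160: parietal/R
  A161: parieto-occipital/L
  A162: parieto-occipital/L
  A163: parieto-occipital/L
  A164: parieto-occipital/L
  A165: parieto-occipital/L
  A166: parieto-occipital/L
  A167: parieto-occipital/L
  A168: parieto-occipital/L
  A169: parieto-occipital/L
  A170: parieto-occipital/L
  A171: parieto-occipital/L
  A172: parieto-occipital/L
  A173: parieto-occipital/L
  A174: parieto-occipital/L
  A175: parieto-occipital/L
  A176: parieto-occipital/L
  A177: parieto-occipital/L
  A178: parieto-occipital/L
  A179: parieto-occipital/L
  A180: parieto-occipital/L
  A181: parieto-occipital/L
  A182: parieto-occipital/L
  A183: parieto-occipital/R
  A184: parieto-occipital/R
  A185: parieto-occipital/R
  A186: parieto-occipital/R
  A187: parieto-occipital/R
  A188: parieto-occipital/R
  A189: parieto-occipital/R
  A190: parieto-occipital/R
  A191: parieto-occipital/R
  A192: parieto-occipital/R
  A193: parieto-occipital/R
  A194: parieto-occipital/R
  A195: parieto-occipital/R
  A196: parieto-occipital/R
  A197: parieto-occipital/R
  A198: parieto-occipital/R
  A199: parieto-occipital/R
  A200: parieto-occipital/R
  A201: parieto-occipital/R
  A202: parieto-occipital/R
  A203: parieto-occipital/R
  A204: parieto-occipital/R
  A205: occipital/L
  A206: occipital/L
  A207: occipital/L
  A208: occipital/L
  A209: occipital/L
  A210: occipital/L
  A211: occipital/L
  A212: occipital/L
  A213: occipital/L
  A214: occipital/L
  A215: occipital/L
  A216: occipital/L
  A217: occipital/L
  A218: occipital/L
  A219: occipital/L
  A220: occipital/L
  A221: occipital/L
  A222: occipital/L
  A223: occipital/L
  A224: occipital/L
  A225: occipital/L
  A226: occipital/L
  A227: occipital/R
  A228: occipital/R
  A229: occipital/R
  A230: occipital/R
  A231: occipital/R
  A232: occipital/R
  A233: occipital/R
  A234: occipital/R
  A235: occipital/R
  A236: occipital/R
  A237: occipital/R
  A238: occipital/R
  A239: occipital/R
  A240: occipital/R
  A241: occipital/R
  A242: occipital/R
  A243: occipital/R
  A244: occipital/R
  A245: occipital/R
  A246: occipital/R
  A247: occipital/R
  A248: occipital/R
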