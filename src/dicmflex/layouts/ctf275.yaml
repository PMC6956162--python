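system: ctf275
channels:
  M1: frontal/L
  M2: frontal/L
  M3: frontal/L
  M4: frontal/L
  M5: frontal/L
  M6: frontal/L
  M7: frontal/L
  M8: frontal/L
  M9: frontal/L
  M10: frontal/L
  M11: frontal/L
  M12: frontal/L
  M13: frontal/L
  M14: frontal/L
  M15: frontal/L
  M16: frontal/L
  M17: frontal/L
  M18: frontal/L
  M19: frontal/L
  M20: frontal/L
  M21: frontal/L
  M22: frontal/L
  M23: frontal/L
  M24: frontal/L
  M25: frontal/L
  M26: frontal/L
  M27: frontal/L
  M28: frontal/L
  M29: frontal/L
  M30: frontal/L
  M31: frontal/L
  M32: frontal/L
  M33: frontal/L
  M34: frontal/R
  M35: frontal/R
  M36: frontal/R
  M37: frontal/R
  M38: frontal/R
  M39: frontal/R
  M40: frontal/R
  M41: frontal/R
  M42: frontal/R
  M43: frontal/R
  M44: frontal/R
  M45: frontal/R
  M46: frontal/R
  M47: frontal/R
  M48: frontal/R
  M49: frontal/R
  M50: frontal/R
  M51: frontal/R
  M52: frontal/R
  M53: frontal/R
  M54: frontal/R
  M55: frontal/R
  M56: frontal/R
  M57: frontal/R
  M58: frontal/R
  M59: frontal/R
  M60: frontal/R
  M61: frontal/R
  M62: frontal/R
  M63: frontal/R
  M64: frontal/R
  M65: frontal/R
  M66: frontal/R
  M67: temporal/L
  M68: temporal/L
  M69: temporal/L
  M70: temporal/L
  M71: temporal/L
  M72: temporal/L
  M73: temporal/L
  M74: temporal/L
  M75: temporal/L
  M76: temporal/L
  M77: temporal/L
  M78: temporal/L
  M79: temporal/L
  M80: temporal/L
  M81: temporal/L
  M82: temporal/L
  M83: temporal/L
  M84: temporal/L
  M85: temporal/L
  M86: temporal/L
  M87: temporal/L
  M88: temporal/L
  M89: temporal/L
  M90: temporal/L
  M91: temporal/L
  M92: temporal/L
  M93: temporal/L
  M94: temporal/L
  M95: temporal/L
  M96: temporal/R
  M97: temporal/R
  M98: temporal/R
  M99: temporal/R
  M100: temporal/R
  M101: temporal/R
  M102: temporal/R
  M103: temporal/R
  M104: temporal/R
  M105: temporal/R
  M106: temporal/R
  M107: temporal/R
  M108: temporal/R
  M109: temporal/R
  M110: temporal/R
  M111: temporal/R
  M112: temporal/R
  M113: temporal/R
  M114: temporal/R
  M115: temporal/R
  M116: temporal/R
  M117: temporal/R
  M118: temporal/R
  M119: temporal/R
  M120: temporal/R
  M121: temporal/R
  M122: temporal/R
  M123: temporal/R
  M124: temporal/R
  M125: parietal/L
  M126: parietal/L
  M127: parietal/L
  M128: parietal/L
  M129: parietal/L
  M130: parietal/L
  M131: parietal/L
  M132: parietal/L
  M133: parietal/L
  M134: parietal/L
  M135: parietal/L
  M136: parietal/L
  M137: parietal/L
  M138: parietal/L
  M139: parietal/L
  M140: parietal/L
  M141: parietal/L
  M142: parietal/L
  M143: parietal/L
  M144: parietal/L
  M145: parietal/L
  M146: parietal/L
  M147: parietal/L
  M148: parietal/L
  M149: parietal/L
  M150: parietal/L
  M151: parietal/L
  M152: parietal/R
  M153: parietal/R
  M154: parietal/R
  M155: parietal/R
  M156: parietal/R
  M157: parietal/R
  M158: parietal/R
  M159: parietal/R
  M160: parietal/R
  M161: parietal/R
  M162: parietal/R
  M163: parietal/R
  M164: parietal/R
  M165: parietal/R
  M166: parietal/R
  M167: parietal/R
  M168: parietal/R
  M169: parietal/R
  M170: parietal/R
  M171: parietal/R
  M172: parietal/R
  M173: parietal/R
  M174: parietal/R
  M175: parietal/R
  M176: parietal/R
  M177: parietal/R
  M178: parietal/R
  M179: parieto-occipital/L
  M180: parieto-occipital/L
  M181: parieto-occipital/L
  M182: parieto-occipital/L
  M183: parieto-occipital/L
  M184: parieto-occipital/L
  M185: parieto-occipital/L
  M186: parieto-occipital/L
  M187: parieto-occipital/L
  M188: parieto-occipital/L
  M189: parieto-occipital/L
  M190: parieto-occipital/L
  M191: parieto-occipital/L
  M192: parieto-occipital/L
  M193: parieto-occipital/L
  M194: parieto-occipital/L
  M195: parieto-occipital/L
  M196: parieto-occipital/L
  M197: parieto-occipital/L
  M198: parieto-occipital/L
  M199: parieto-occipital/L
  M200: parieto-occipital/L
  M201: parieto-occipital/L
  M202: parieto-occipital/L
  M203: parieto-occipital/L
  M204: parieto-occipital/R
  M205: parieto-occipital/R
  M206: parieto-occipital/R
  M207: parieto-occipital/R
  M208: parieto-occipital/R
  M209: parieto-occipital/R
  M210: parieto-occipital/R
  M211: parieto-occipital/R
  M212: parieto-occipital/R
  M213: parieto-occipital/R
  M214: parieto-occipital/R
  M215: parieto-occipital/R
  M216: parieto-occipital/R
  M217: parieto-occipital/R
  M218: parieto-occipital/R
  M219: parieto-occipital/R
  M220: parieto-occipital/R
  M221: parieto-occipital/R
  M222: parieto-occipital/R
  M223: parieto-occipital/R
  M224: parieto-occipital/R
  M225: parieto-occipital/R
  M226: parieto-occipital/R
  M227: parieto-occipital/R
  M228: parieto-occipital/R
  M229: occipital/L
  M230: occipital/L
  M231: occipital/L
  M232: occipital/L
  M233: occipital/L
  M234: occipital/L
  M235: occipital/L
  M236: occipital/L
  M237: occipital/L
  M238: occipital/L
  M239: occipital/L
  M240: occipital/L
  M241: occipital/L
  M242: occipital/L
  M243: occipital/L
  M244: occipital/L
  M245: occipital/L
  M246: occipital/L
  M247: occipital/L
  M248: occipital/L
  M249: occipital/L
  M250: occipital/L
  M251: occipital/L
  M252: occipital/L
  M253: occipital/R
  M254: occipital/R
  M255: occipital/R
  M256: occipital/R
  M257: occipital/R
  M258: occipital/R
  M259: occipital/R
  M260: occipital/R
  M261: occipital/R
  M262: occipital/R
  M263: occipital/R
  M264: occipital/R
  M265: occipital/R
  M266: occipital/R
  M267: occipital/R
  M268: occipital/R
  M269: occipital/R
  M270: occipital/R
  M271: occipital/R
  M272: occipital/R
  M273: occipital/R
  M274: occipital/R
  M275: occipital/R
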