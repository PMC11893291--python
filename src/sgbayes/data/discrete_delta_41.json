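{
 "values": [
  -2.0,
  -1.9,
  -1.8,
  -1.7,
  -1.6,
  -1.5,
  -1.4,
  -1.3,
  -1.2,
  -1.1,
  -1.0,
  -0.9,
  -0.8,
  -0.7,
  -0.6,
  -0.5,
  -0.4,
  -0.3,
  -0.2,
  -0.1,
  0.0,
  0.1,
  0.2,
  0.3,
  0.4,
  0.5,
  0.6,
  0.7,
  0.8,
  0.9,
  1.0,
  1.1,
  1.2,
  1.3,
  1.4,
  1.5,
  1.6,
  1.7,
  1.8,
  1.9,
  2.0
 ],
 "probs": [
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025,
  0.024390243902439025
 ]
}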