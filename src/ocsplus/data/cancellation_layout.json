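{
 "schema": "ocsplus-cancellation-layout/1",
 "description": "Synthetic 30-target / 20-distractor search array (axis-aligned boxes, screen pixels, origin top-left).",
 "items": [
  {
   "id": "t01",
   "role": "target",
   "x": 20,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "t02",
   "role": "target",
   "x": 130,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "t03",
   "role": "target",
   "x": 240,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "d01",
   "role": "distractor",
   "x": 350,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "d02",
   "role": "distractor",
   "x": 460,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "t04",
   "role": "target",
   "x": 570,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "t05",
   "role": "target",
   "x": 680,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "t06",
   "role": "target",
   "x": 790,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "d03",
   "role": "distractor",
   "x": 900,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "d04",
   "role": "distractor",
   "x": 1010,
   "y": 20,
   "w": 80,
   "h": 80
  },
  {
   "id": "t07",
   "role": "target",
   "x": 20,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "t08",
   "role": "target",
   "x": 130,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "t09",
   "role": "target",
   "x": 240,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "d05",
   "role": "distractor",
   "x": 350,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "d06",
   "role": "distractor",
   "x": 460,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "t10",
   "role": "target",
   "x": 570,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "t11",
   "role": "target",
   "x": 680,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "t12",
   "role": "target",
   "x": 790,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "d07",
   "role": "distractor",
   "x": 900,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "d08",
   "role": "distractor",
   "x": 1010,
   "y": 130,
   "w": 80,
   "h": 80
  },
  {
   "id": "t13",
   "role": "target",
   "x": 20,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "t14",
   "role": "target",
   "x": 130,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "t15",
   "role": "target",
   "x": 240,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "d09",
   "role": "distractor",
   "x": 350,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "d10",
   "role": "distractor",
   "x": 460,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "t16",
   "role": "target",
   "x": 570,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "t17",
   "role": "target",
   "x": 680,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "t18",
   "role": "target",
   "x": 790,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "d11",
   "role": "distractor",
   "x": 900,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "d12",
   "role": "distractor",
   "x": 1010,
   "y": 240,
   "w": 80,
   "h": 80
  },
  {
   "id": "t19",
   "role": "target",
   "x": 20,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "t20",
   "role": "target",
   "x": 130,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "t21",
   "role": "target",
   "x": 240,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "d13",
   "role": "distractor",
   "x": 350,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "d14",
   "role": "distractor",
   "x": 460,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "t22",
   "role": "target",
   "x": 570,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "t23",
   "role": "target",
   "x": 680,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "t24",
   "role": "target",
   "x": 790,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "d15",
   "role": "distractor",
   "x": 900,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "d16",
   "role": "distractor",
   "x": 1010,
   "y": 350,
   "w": 80,
   "h": 80
  },
  {
   "id": "t25",
   "role": "target",
   "x": 20,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "t26",
   "role": "target",
   "x": 130,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "t27",
   "role": "target",
   "x": 240,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "d17",
   "role": "distractor",
   "x": 350,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "d18",
   "role": "distractor",
   "x": 460,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "t28",
   "role": "target",
   "x": 570,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "t29",
   "role": "target",
   "x": 680,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "t30",
   "role": "target",
   "x": 790,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "d19",
   "role": "distractor",
   "x": 900,
   "y": 460,
   "w": 80,
   "h": 80
  },
  {
   "id": "d20",
   "role": "distractor",
   "x": 1010,
   "y": 460,
   "w": 80,
   "h": 80
  }
 ]
}
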