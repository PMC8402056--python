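{
 "version": "3.16.7",
 "flags": {},
 "shapes": [
  {
   "label": "ear",
   "points": [
    [
     3,
     5
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     10,
     2
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     7,
     7
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     0,
     0
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     31,
     14
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     14,
     31
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     20,
     20
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     9,
     25
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     25,
     9
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     1,
     30
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     30,
     1
    ]
   ],
   "shape_type": "point",
   "group_id": null
  },
  {
   "label": "ear",
   "points": [
    [
     18,
     6
    ]
   ],
   "shape_type": "point",
   "group_id": null
  }
 ],
 "imagePath": "sim_00000.png",
 "imageHeight": 32,
 "imageWidth": 32
}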