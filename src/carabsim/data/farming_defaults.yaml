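# Default crop management plans and farm-type rotations.
#
# These are configurable, literature-typical defaults for temperate (Dutch)
# arable systems; none of the windows or probabilities are measured values.
# Windows are day-of-year (365-day calendar, doy 59 = March 1); probability
# is the chance the activity is carried out in a given season. Insecticide
# applications are confined to intensively sprayed crops (potatoes,
# vegetables, flower bulbs).
crops:
  winter_wheat:
    events:
      - {type: plough, start: 60, end: 90, probability: 0.9}
      - {type: harrow, start: 70, end: 100, probability: 0.8}
      - {type: sow, start: 80, end: 110, probability: 1.0}
      - {type: fertilize, start: 100, end: 140, probability: 0.9}
      - {type: fungicide_spray, start: 150, end: 180, probability: 0.7}
      - {type: harvest, start: 210, end: 240, probability: 1.0}
  spring_barley:
    events:
      - {type: plough, start: 60, end: 90, probability: 0.9}
      - {type: sow, start: 85, end: 110, probability: 1.0}
      - {type: fertilize, start: 100, end: 130, probability: 0.8}
      - {type: harvest, start: 215, end: 240, probability: 1.0}
  maize:
    events:
      - {type: plough, start: 90, end: 120, probability: 0.9}
      - {type: sow, start: 110, end: 135, probability: 1.0}
      - {type: fertilize, start: 120, end: 150, probability: 0.9}
      - {type: harvest, start: 260, end: 290, probability: 1.0}
  sugar_beet:
    events:
      - {type: plough, start: 70, end: 100, probability: 0.9}
      - {type: sow, start: 95, end: 120, probability: 1.0}
      - {type: herbicide_spray, start: 130, end: 160, probability: 0.8}
      - {type: harvest, start: 270, end: 300, probability: 1.0}
  potato:
    events:
      - {type: plough, start: 80, end: 110, probability: 0.9}
      - {type: sow, start: 100, end: 125, probability: 1.0}
      - {type: fungicide_spray, start: 150, end: 190, probability: 0.9}
      - {type: insecticide_spray, start: 145, end: 175, probability: 0.9, product: insecticide}
      - {type: insecticide_spray, start: 170, end: 200, probability: 0.8, product: insecticide}
      - {type: insecticide_spray, start: 195, end: 225, probability: 0.6, product: insecticide}
      - {type: harvest, start: 250, end: 280, probability: 1.0}
  vegetables:
    events:
      - {type: plough, start: 70, end: 100, probability: 0.9}
      - {type: sow, start: 95, end: 125, probability: 1.0}
      - {type: insecticide_spray, start: 140, end: 175, probability: 0.9, product: insecticide}
      - {type: insecticide_spray, start: 170, end: 205, probability: 0.8, product: insecticide}
      - {type: insecticide_spray, start: 200, end: 235, probability: 0.5, product: insecticide}
      - {type: harvest, start: 240, end: 280, probability: 1.0}
  tulip:
    events:
      - {type: fertilize, start: 60, end: 90, probability: 0.8}
      - {type: insecticide_spray, start: 120, end: 155, probability: 0.9, product: insecticide}
      - {type: insecticide_spray, start: 150, end: 185, probability: 0.7, product: insecticide}
      - {type: harvest, start: 185, end: 215, probability: 1.0}
  grassland:
    events:
      - {type: fertilize, start: 70, end: 110, probability: 0.9}
      - {type: grass_cut, start: 140, end: 160, probability: 0.9}
      - {type: grass_cut, start: 180, end: 200, probability: 0.8}
      - {type: grass_cut, start: 220, end: 245, probability: 0.7}

# Crop shares per farm type; counts sum to 100 (one entry per 1 % of area).
rotations:
  animal_grazing: {grassland: 80, maize: 20}
  arable: {winter_wheat: 30, spring_barley: 20, potato: 25, sugar_beet: 25}
  arable_vegetable: {vegetables: 40, potato: 20, winter_wheat: 20, spring_barley: 20}
  starch_potato: {potato: 50, winter_wheat: 25, spring_barley: 25}
  flower: {tulip: 40, winter_wheat: 30, spring_barley: 30}
  other: {winter_wheat: 50, grassland: 50}
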