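# Ingredient classes for the fruits/vegetables/legumes component.
# Classes fruit, vegetable and legume qualify under both algorithm
# versions; nut and qualifying_oil (rapeseed, walnut, olive) qualify
# only under the old algorithm.  Unlisted ingredients are treated as
# non-qualifying.  This map is editable configuration: extend it to
# match the ingredient vocabulary of your own product data.

fruit:
  - apple
  - banana
  - mango
  - strawberry
  - raspberry
  - blueberry
  - orange
  - lemon
  - coconut        # fruit flesh; coconut oil does not qualify
  - date
  - tomato

vegetable:
  - carrot
  - onion
  - garlic
  - leek
  - spinach
  - beetroot
  - bell pepper
  - paprika
  - courgette
  - zucchini
  - mushroom
  - broccoli
  - cauliflower
  - pumpkin
  - sweet potato

legume:
  - pea
  - chickpea
  - lentil
  - soybean
  - soy
  - lupin
  - black bean
  - kidney bean
  - white bean
  - faba bean

nut:
  - almond
  - cashew
  - hazelnut
  - walnut
  - peanut
  - pecan
  - macadamia

qualifying_oil:
  - rapeseed oil
  - canola oil
  - walnut oil
  - olive oil
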